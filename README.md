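# arborgen

Generation of realistic dendritic morphologies by estimating the spatial
heterogeneity of dendritic branching.

Dendritic bifurcations along each soma-to-tip path are modeled as a
heterogeneous Poisson point process whose log-rate follows a latent AR(1)
state. A point-process filter, fixed-interval smoother, and EM estimate the
branching rate as a function of (normalized) pathlength from the soma. New
morphologies are grown by thinning homogeneous point processes against the
estimated rate, placing stems on a cone, drawing bifurcation amplitude and
azimuth from conditional (x, z)-binned histograms, and terminating every
branch at a sampled anatomical boundary pathlength. A morphometric suite
(Sholl profiles, dendritic length by distance and per layer, distribution
RMSE, conditional heatmaps) and a passive-electrical suite (series/parallel
proximal current fractions with quadratic regression, spine-weighted somatic
current) validate generated populations against references.

## Layout

| module | contents |
| --- | --- |
| `arborgen.trees` | SWC I/O, tree model, registration, terminal paths, point-process encoding |
| `arborgen.ratefilter` | state-space model, filter, smoother, EM, rate estimation |
| `arborgen.growth` | angle tables, stem placement, thinning, recursive growth, screening, rescaling, populations |
| `arborgen.metrics` | morphometrics, Sholl, heatmaps, distribution RMSE, TDL profiles |
| `arborgen.passive` | proximal current fractions, quadratic fits, spine-weighted current |
| `arborgen.synth` | synthetic point processes, toy trees, reference populations with known rates |
| `arborgen.cli` | `arborgen` command-line interface |

## CLI

```sh
# estimate a branching rate from a directory of SWC reconstructions
arborgen estimate path/to/swc_dir --bins 100 --normalize --out out/rate

# generate a screened population from a JSON config
arborgen generate --config config.json --n 50 --mode heterogeneous \
    --seed 1 --out out/population

# morphometrics (and pairwise distribution RMSE with >= 2 populations)
arborgen measure out/population reference_dir --out out/metrics

# proximal current fractions + pooled quadratic fit
arborgen electro out/population --points 100 --seed 1 --out out/electro
```

Configs are JSON documents mirroring `growth.GenerationConfig` (empirical
distributions embedded as value lists; see `GenerationConfig.save/load`).
Every command is deterministic given its inputs and `--seed`, writes a
`manifest.json` into its output directory, and refuses to overwrite non-empty
output directories without `--force`.

## Notes

- Estimation with `tip_events=False` treats dendritic tips as extent markers
  rather than bifurcation events — use this when the estimate will drive
  generation, where termination is imposed by the anatomical boundary.
- `growth.generation_rate_from_estimate` converts a fitted terminal-path
  rate into the per-branch rate used by the grower, by default inverting the
  descendant-tip recounting factor (q = f/(2−f)) so that regenerated
  populations reproduce the encoded per-bin bifurcation frequencies.
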