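# microhemo

Microvascular hemodynamics toolkit for zebrafish tail-amputation studies:
a Poiseuille hydraulic model of the trunk vasculature with discrete
red-cell transport, centerline cell tracking for time-lapse fluorescence
movies, two-regime wall-shear-stress (WSS) statistics, and Otsu-mask
colocalization — all exercisable on synthetic data with exact ground truth.

## Components

| module | what it does |
| --- | --- |
| `microhemo.network` | Trunk ladder network (DA/PCV/DLAV rails, SeA/SeV rungs, distal ECL anastomosis), Poiseuille + per-cell occlusive resistances, Kirchhoff flow solver, flux-biased (plasma-skimming) cell routing, amputation, WSS set-point radius adaptation |
| `microhemo.imaging` | Synthetic time-lapse movies (Gaussian PSF blobs, gaussian/poisson noise) and two-channel colocalization fixtures with exact truth |
| `microhemo.tracking` | Centerline intensity profiles, peak detection with sub-pixel refinement, peak coalescence (3 um), nearest-neighbour frame linking (30 um cutoff), majority-rule direction filtering, per-vessel density/velocity summaries |
| `microhemo.wss` | Plasma WSS `4*mu*v/r` and cell-adjacent WSS with the occlusive term `pi*r^3*v*alpha_c/(2*l)`, the pooled 0.975-quantile plasma threshold, and the peak-shear-stress-portion statistic |
| `microhemo.coloc` | Exhaustive multilevel Otsu thresholds, binary masks, overlap, 20–500 px connected-component filter |
| `microhemo.experiments` | Pre/post-amputation comparison with per-SeA fold-change table |
| `microhemo.cli` | `simulate`, `track`, `wss`, `coloc`, `amputation-experiment` commands |

Units: micrometres for geometry, cm/s for reported velocities, dyne/cm^2
for stresses (1 Pa = 10 dyne/cm^2), cells/cm for number densities.

## CLI

```sh
# solve the default trunk, transport cells, render a movie + ground truth
microhemo simulate --n-se-pairs 16 --duration 20 --seed 1 --outdir out/sim

# track a movie along traced centerlines (sidecar JSON supplies pixel size
# and frame rate)
microhemo track --movie out/sim/movie.tif \
    --centerlines out/sim/centerlines.csv --outdir out/trk

# WSS decomposition, pooled threshold, peak portions
microhemo wss --stats out/trk/stats.csv --detections out/trk/detections.csv \
    --alpha-c 1e15 --outdir out/wss

# two-channel colocalization report
microhemo coloc --channel-a a.tif --channel-b b.tif --outdir out/col

# intact vs amputated per-SeA fold-change table
microhemo amputation-experiment --seed 1 --outdir out/amp
```

Every command accepts `--config config.yaml` (per-command sections; flags
override), `--seed`, `--outdir` and `--log-level`, and writes a
`manifest.json` with a config echo and SHA-256 checksums of its outputs.
Identical config + seed gives byte-identical CSV outputs.

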