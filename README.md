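# saltatrack

Single-particle tracking and motion-type classification for live-cell
cargo-transport movies — the analysis used to ask whether fluorescently
tagged retroviral capsids (Gag-GFP puncta) are hauled along microtubules.
Time-lapse fluorescence stacks (e.g. one frame every 5 s for 2 min) are
reduced to per-particle trajectories, each trajectory is measured and
assigned to one of three motion populations, and trajectories are tested
for colocalization with a filament (tubulin) channel. A seeded synthetic
movie generator reproduces the whole imaging regime so that every stage is
testable against known ground truth.

Intended users: cell biologists and image analysts quantifying intracellular
transport from widefield/confocal time-lapse data, and method developers who
need a labelled tracking benchmark.

## The measurements

For a trajectory with positions $(x_n, y_n)$ in pixels, frame interval $t$
seconds and pixel size in nm/px:

- **instantaneous velocity** at frame $n$ (nm/s):

$$v_n = \frac{\sqrt{(x_{n+1}-x_n)^2 + (y_{n+1}-y_n)^2}}{t} \times \text{pixel\_size}$$

- **maximum instantaneous velocity** $v_{\max} = \max_n v_n$ per trajectory;
- **total displacement** (px) between the trajectory's endpoints:

$$d_{\text{total}} = \sqrt{(x_{\text{last}}-x_{\text{first}})^2 + (y_{\text{last}}-y_{\text{first}})^2}$$

- the time-averaged **MSD** curve and its log-log slope $\alpha$
  (confined $\alpha<1$, diffusive $\alpha\approx 1$, ballistic
  $\alpha\approx 2$), and the straightness ratio $d_{\text{total}}/L_{path}$.

Trajectories observed in fewer than 10 frames are discarded before any
population statistic. Each survivor is classified

- **P1 restricted** if $d_{\text{total}} \le T_1$ (default 2 px),
- **P3 directed** if $v_{\max} \ge T_v$ (default 150 nm/s), or
  $\alpha \ge T_\alpha$ (1.4) with $d_{\text{total}} \ge T_3$ (10 px),
- **P2 Brownian** otherwise,

and populations are compared with two-sided Mann-Whitney U tests on
$d_{\text{total}}$ (exact by enumeration for small samples, tie-corrected
normal approximation otherwise). See `docs/methods.md` for the rationale
behind each threshold and the simulator's motion models.

Pipeline stages: Gaussian-matched-filter **spot detection** with sub-pixel
moment refinement → exact cost-minimizing **frame-to-frame linking** with
gap closing (Hungarian assignment, squared-displacement cost, dummy
appearance/disappearance costs) → **trajectory statistics** →
**classification** → **trajectory–filament colocalization** (median
point-to-polyline distance against a threshold, default 250 nm).

## Worked example

```sh
$ saltatrack demo --seed 7 --out demo_out
demo complete: 478 spots, 20 trajectories, 20 after length filter
  P1_RESTRICTED: n=4 fraction=0.20 median d_total=1.32 px
  P2_BROWNIAN: n=6 fraction=0.30 median d_total=5.44 px
  P3_DIRECTED: n=10 fraction=0.50 median d_total=78.81 px
```

This simulates a 2-minute, 5-s-interval movie of 20 particles (15/41/44%
mixture of anchored, freely diffusing, and filament-riding particles),
detects and links the spots, filters to trajectories with ≥ 10 frames, and
classifies them. Here all 20 particles were tracked through all 24 frames;
the three recovered populations separate cleanly in median net displacement
(1.3 px anchored vs 5.4 px diffusing vs 79 px transported). `demo_out/`
contains the movie (`movie.tif`), ground truth, per-stage CSVs, a
`populations.json` summary with the pairwise Mann-Whitney tests, a
trajectory gallery and a displacement dot plot. Running the same command
twice produces byte-identical summaries.

The same stages are available individually (`saltatrack simulate / detect /
track / analyze / classify / coloc / run`) for user-supplied TIFF stacks;
see `--help` on each.

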