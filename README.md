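# mirtrack

Single-particle tracking and fluorescence fluctuation analysis for
live-cell miRNA imaging.

When fluorescently labeled pre-miRNA is introduced into living cells, its
fate can be followed with single-molecule-sensitive microscopy: HILO movies
at 20 Hz show individual miRNA particles moving through the cytoplasm,
confocal photon-count recordings report duplex dissociation through the
decay of the two-color cross-correlation amplitude, and two-channel movies
reveal colocalization of a miRNA with its target mRNA. `mirtrack`
implements the complete quantitative pipeline for such experiments —

* **Detection** — per-frame spot detection with a difference-of-Gaussian
  (DoG) filter (spot diameter 0.5 μm, absolute quality cut 50) and
  sub-pixel localization;
* **Linking** — nearest-neighbor trajectory assembly with a hard
  displacement gate (0.4 μm/frame) and a track-duration filter (≥ 2.8 s);
* **Motion classification** — time-averaged MSD curves,
  `MSD(nΔt) = Σᵢ[(x₍ᵢ₊ₙ₎−xᵢ)² + (y₍ᵢ₊ₙ₎−yᵢ)²]/(#pairs)`,
  and a four-way decision tree: D ≤ 0.01 μm²/s (from lags 2–11) ⇒
  *stationary*; confined-model fit `MSD(t) = (4R²conf/3)(1 − e^(−t/τ))`
  over lags 2–30 with τ ≤ 30 frames ⇒ *confined*; otherwise
  `MSD = a·t²` with a > 4D×1.2 ⇒ *directed*, else *diffusive*;
* **FCS / FCCS** — a multiple-tau-grid correlator,
  `G(τ)−1 = (1/N)·(1+τ/τ₁)⁻¹·[1+(τ/τ₁)/κ²]^(−1/2)` model fits with the
  structure parameter κ fixed (10–15), relative cross-correlation
  amplitudes, and exponential fits of the normalized amplitude decay that
  yield the duplex-dissociation time constant;
* **Quantification** — object-based two-color colocalization percentages,
  co-moving trajectory pairs, and background-subtracted ROI intensity
  ratios (cytoplasmic retention, perinuclear fraction);
* **Synthetic microscope** — generators for every input with known ground
  truth: trajectories in all four motion modes, rendered Poisson movies
  with integrated-Gaussian PSFs, two-channel FCS traces from diffusers in a
  3-D Gaussian observation volume, planted colocalization sets, and noisy
  exponential amplitude series.

Since the original raw movies are not public, the synthetic module is the
package's reference data source: every stage is validated against planted
ground truth.

## Worked example

Full synthetic round trip — simulate 50 particles (12 stationary,
13 confined, 13 free, 12 directed) for 300 frames at 20 Hz, render the
movie, detect, link and classify:

```python
from mirtrack.pipeline import default_config, run_pipeline

result = run_pipeline({**default_config(), "seed": 0}, "runs/demo")
print(result["summary"].counts)
print({k: round(v, 3) for k, v in result["summary"].fractions_all.items()})
```

prints

```
{'stationary': 12, 'confined': 13, 'diffusive': 13, 'directed': 12}
{'stationary': 0.24, 'confined': 0.26, 'diffusive': 0.26, 'directed': 0.24}
```

— every planted particle is recovered as one track and assigned its true
motion mode: the recovered fractions equal the planted ones. The run
directory contains the detection/track/classification tables and a
manifest with the config hash and seed; re-running the same config
reproduces the tables byte-for-byte.

Duplex-dissociation kinetics from a synthetic FCCS amplitude series
(normalized to 1 at the first observation, fitted with
`exp(−(t−t₀)/τ)`):

```python
from mirtrack.synthetic import simulate_amplitude_series
from mirtrack.correlation import fit_amplitude_decay

series = simulate_amplitude_series(43.4, [2, 20, 40, 60, 80, 100, 120],
                                   noise_sd=0.05, seed=1)
print(round(fit_amplitude_decay(series).tau_decay, 1))   # 44.1
```

The same stages are available on the command line:

```sh
mirtrack run --out runs/demo --seed 0
mirtrack detect movie.tif --diameter-um 0.5 --quality 50 --out det.csv
mirtrack track det.csv --max-disp-um 0.4 --min-duration-s 2.8 --out trk.csv
mirtrack classify trk.csv --out cls.csv
mirtrack coloc detA.csv detB.csv --radius-um 0.3
```

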