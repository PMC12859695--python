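# wormassay

Quantification of *Caenorhabditis* plate-assay behavior: chemotaxis-index
scoring, worm locomotion kinematics, pirouette (sharp-reorientation)
detection, and the rank-based statistics used to compare species and
conditions — together with a synthetic worm-track and plate-assay
generator so every stage can be verified by parameter recovery against
known ground truth.

It is aimed at researchers analyzing exports from plate-scale worm
trackers (per-animal centroid and head-tip time series) and endpoint
counts from two-point chemotaxis plates, for example when contrasting
*C. elegans* with slower, head-swinging relatives such as *C. inopinata*.

## What it computes

**Chemotaxis index.** For a two-point plate with worm counts A (control
zone), B (odorant zone) and C (central 1-cm band, excluded):

    CI = (B − A) / (A + B),   CI ∈ [−1, 1]

The per-plate CI is the unit of analysis. Counts are odorant-anchored, so
alternating the physical odorant side across trials is a no-op.

**Kinematics.** Instantaneous speed is frame-to-frame centroid
displacement over the frame interval. Per-animal speed is the median
after excluding tracking gaps and immobile steps (< 0.2 mm/s); animals
whose median exceeds the 0.5 mm/s tracker ceiling are excluded as
outliers. Track length sums Euclidean step distances over valid steps
(gaps excised, never bridged), and the head-swinging index is

    HSI = head track length / centroid track length,

a dimensionless measure of lateral head oscillation (klinotaxis-style
scanning); HSI = 1 for a worm that never swings its head.

**Pirouettes.** An event fires when the cumulative (net signed) turning
of the centroid heading exceeds 120° within a 3-s window *and* mean
speed over the same window drops ≥ 40% below the 2-s pre-event baseline.
Overlapping candidates merge (1-s refractory); rates are events·min⁻¹ of
valid observation time. Headings are computed on a 0.5-s resampled
timebase to keep positional jitter out of the turning signal.

**Statistics.** Two-sided Wilcoxon rank-sum (exact by enumeration for
small tie-free samples), median-difference effect sizes with percentile
bootstrap 95% CIs, and Kruskal–Wallis followed by Dunn's pairwise
z-tests with Benjamini–Hochberg adjustment.

## Worked example

Score simulated attraction plates and compare the two shipped synthetic
species presets end to end:

```python
import pandas as pd
from wormassay import (EndpointModel, simulate_plates, chemotaxis_index,
                       ELEGANS_LIKE, INOPINATA_LIKE, make_two_species_study,
                       summarize_track, detect_pirouettes, pirouette_rate,
                       compare_conditions)

# strong-attraction plates: 10 worms, zone probabilities (0.2, 0.7, 0.1)
for p in simulate_plates(EndpointModel(0.2, 0.7, 0.1), 3, seed=4):
    r = chemotaxis_index(p)
    print(p.plate_id, p.count_control, p.count_odorant, p.count_central, r.ci)

tracks = make_two_species_study(INOPINATA_LIKE, ELEGANS_LIKE, 10,
                                duration=300, dt=0.1, seed=42)
rows = []
for tr in tracks:
    s = summarize_track(tr)
    rows.append({"group": tr.meta["group"],
                 "median_speed": s.median_speed,
                 "hsi": s.head_swinging_index,
                 "rate": pirouette_rate(tr, detect_pirouettes(tr)).rate})
df = pd.DataFrame(rows)
print(df.groupby("group").median().round(3))
(res,) = compare_conditions(df, "group", "hsi", seed=0)
print(res.p_value, res.effect_size, (res.ci_low, res.ci_high))
```

Output:

```
sim-0000 1 9 0 0.8
sim-0001 0 8 2 1.0
sim-0002 0 9 1 1.0
                median_speed    hsi   rate
group
elegans-like           0.387  1.254  0.418
inopinata-like         0.276  4.036  0.000
```

The three plates are strongly attractive (CI near +1: most worms reached
the odorant zone). The group medians reproduce the intended contrasts:
the inopinata-like worms crawl more slowly (0.276 vs 0.387 mm/s), swing
their heads far more (HSI 4.04 vs 1.25 — the head path is four times the
centroid path) and essentially never pirouette (0 vs 0.42 events/min).
The Wilcoxon comparison of the head-swinging index gives p ≈ 1.8e-4 with
a median difference of +2.78 (bootstrap 95% CI [2.75, 2.81]).

A command-line interface mirrors the library
(`wormassay simulate|kinematics|pirouettes|ci|stats`, see `--help`).

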