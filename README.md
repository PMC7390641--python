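# tectodist

Visual **detection distance** and calcium-transient response metrics from
optic-tectum fluorescence recordings of larval zebrafish watching a moving
prey-like stimulus — with a full synthetic-data generator, so the entire
pipeline runs and is testable without any recordings.

## The problem

A larva is mounted with one eye 1 mm from a miniature OLED display on which
a small cross-shaped glyph (0.63 mm) shuttles along a 6.3 mm horizontal
track at 2.1 mm/s, approaching and receding for 10 cycles. Calcium activity
in the optic tectum is imaged at 50 ms per frame; each approach evokes one
fluorescence transient once the glyph becomes visible to the fish. Because
eye, screen and glyph form a right triangle, the distance at which the
tectum first responds is

```
DD = sqrt((x_onset − b)² + d_es²)
```

with `x_onset` the glyph's lateral track position at response onset, `b` the
track coordinate opposite the eye and `d_es` = 1 mm the eye–screen distance.
Alongside DD, each transient yields a duration (onset→offset), an FWHM
(width at half the amplitude above baseline F_base) and inter-peak intervals
(offset→next onset); all four parameters are compared across temperature
treatments (18, 23, 28 °C) with a skewness-screened battery: one-way ANOVA /
Brown–Forsythe with Scheffé or Tamhane T2 post hocs, or Kruskal–Wallis with
Dunn's test.

Intended users: anyone analysing stimulus-locked single-ROI calcium traces
where stimulus kinematics must be mapped back to a physical detection
threshold, and anyone who wants a controlled test bed for such a pipeline.

## Worked example

```python
from tectodist import simulate_experiment
from tectodist.pipeline import run_experiment

trials, truth = simulate_experiment(n_fish_per_temp=5, seed=42)
table, report = run_experiment([(t.trial_id, t.temperature, t.trace) for t in trials])

print(report["group_means"]["detection_distance"])
# {'18.0': 5.931, '23.0': 4.809, '28.0': 3.372}
p = report["parameters"]["detection_distance"]
print(p["omnibus_test"], p["p_value"])
# brown_forsythe 1.49e-25
```

The recovered group-mean detection distances (5.93, 4.81, 3.37 mm at 18, 23,
28 °C) track the generator's ground truth for this seed (5.94, 4.85,
3.38 mm): the pipeline loses only ~one frame of stimulus travel (≤ 0.105 mm)
per onset. The omnibus test lands on Brown–Forsythe because Levene's test
rejects homogeneity here; all three Tamhane T2 pairwise comparisons are
significant, and `report["group_means"]` shows duration falling and
inter-peak interval rising with temperature.

The same workflow is scriptable from the shell:

```
tectodist simulate --seed 42 --n-per-group 5 --out sim/
tectodist run --traces sim/ --labels labels.csv --out results/
tectodist extract --stack stack.tif --pixel-size-um 0.457 --center 240 240 --out trace.csv
tectodist analyze --trace trace.csv --out peaks.csv
```

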