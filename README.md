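# perfcmr

Semiquantitative analysis of adenosine first-pass perfusion CMR in patients
after coronary bypass surgery.

## The problem

First-pass perfusion CMR acquires one image of each short-axis slice per
heartbeat while a gadolinium bolus transits the left-ventricular (LV) blood
pool and the myocardium. In patients with coronary artery bypass grafts
(CABG), the bolus travels a longer conduit path — longest for a left internal
mammary artery (LIMA) graft — so contrast may arrive *later* in graft-supplied
myocardium even when the graft is fully patent. A reader scrolling the
dynamic series can mistake that delay for a perfusion defect. The question
this package addresses: do territories supplied by patent grafts differ from
native-vessel territories in their semiquantitative perfusion parameters, and
if so, in timing, amplitude, or both?

`perfcmr` implements the full analysis pipeline on ROI-averaged
signal-intensity (SI) time curves, plus a synthetic cohort generator with
known ground truth so every stage can be validated end to end.

## The parameters

For each myocardial segment curve (baseline mean subtracted):

- **upslope** — maximal slope of an ordinary least-squares line over 5
  consecutive frames (3 frames for the LV blood pool, whose bolus is
  shorter), in SI/s;
- **SImax** — peak enhancement during the first pass;
- **relative upslope / relative SImax** — the myocardial value in % of the
  mid-slice LV blood-pool value;
- **T_SI50%max, T_SImax** — time from contrast arrival in the LV blood pool
  (first of two consecutive frames above baseline + 3·SD) to 50% of peak /
  to peak myocardial enhancement, in seconds and in heart beats
  (t · HR / 60, one beat = one image).

Parameters are averaged over individualized perfusion territories in the AHA
16-segment model (segments with late gadolinium enhancement excluded), each
graft territory is paired against the same patient's largest native
territory, and paired differences are tested with an exact Wilcoxon
signed-rank test (full enumeration up to n = 15, normal approximation with
tie and continuity correction beyond). A per-patient **add-up score**,

```
score = Δrel_upslope/rel_upslope_native + Δrel_SImax/rel_SImax_native − ΔT50/T50_native
```

probes whether small deficits accumulate: it is negative when the graft
territory is uniformly worse.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (38 CABG + 20 no-CAD patients, seed 1234):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_extract_parameters.py
python analysis/03_cohort_summary.py
python analysis/04_validation_experiments.py
```

Output of steps 2–3:

```
58 patients, 161 territories, 12 excluded for LGE, 45 native-vs-graft pairs
all grafts vs native (n=45): beat delay 0.63 +/- 0.75 (p=0.0000); add-up score 0.205 +/- 1.488 (p=0.627)
  lima_graft: beat delay 0.84 +/- 0.65 (n=16)
  venous_graft: beat delay 0.51 +/- 0.79 (n=29)
native vs all grafts p-values: rel_upslope 0.274, rel_SImax 0.416, T50 0.0000, Tmax 0.0000
```

Read: graft territories reach peak enhancement about half a beat to one beat
*later* than native territories (most for LIMA grafts), the timing difference
is highly significant, but wash-in speed (relative upslope) and peak
enhancement (relative SImax) do not differ and the add-up score shows no
systematic deficit — delayed arrival without a perfusion-defect signature.
Summary tables land in `results/` (`summary_arms.csv`, `summary_pvalues.csv`,
`summary_deltas.csv`, …), raw curves and figures under `scratch/`.

The same pipeline is available as a CLI for external data
(`perfcmr simulate`, `perfcmr analyze --curves curves.csv --territories
map.json --out DIR`, `perfcmr report --in DIR`); see `perfcmr --help` for the
file formats.

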