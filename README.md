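# painnet

Graph-theoretic analysis of task-evoked brain networks, built around the
question of how the brain regions activated by acute painful heat organize
into functional modules. The pipeline computes **stimulation-weighted
functional connectivity** over a fixed 34-node network of pain-responsive
regions (36 with auditory cortex), decomposes it by **weighted-signed
modularity**, classifies **static / dynamical / connector hubs**, and
contrasts conditions (pain vs. audio) with **paired permutation tests and
FDR**. Because the scan data behind the original analysis are not public, the
package includes a first-class synthetic BOLD generator that plants a known
four-module structure (sensorimotor, medial fronto-parietal, lateral
fronto-parietal, limbic) so the whole chain is testable against ground truth.

Intended users: researchers doing connectome-style analyses of task fMRI who
want a reproducible, fully seeded reference implementation of this analysis
family, or a harness for validating their own variant against planted truth.

## The model in brief

For each session, stimulus events are convolved with the canonical
double-gamma HRF, the undershoot is clamped to zero, and the result weights a
Pearson correlation between every pair of node time series:

    r_w(x, y) = cov_w(x, y) / sqrt(var_w(x) var_w(y)),
    cov_w(x, y) = Σ_t w_t (x_t − m_x)(y_t − m_y) / Σ_t w_t

so volumes acquired while the evoked response is high dominate the estimate.
Session matrices are Fisher-z transformed (z = atanh r), averaged per subject,
density-thresholded (top d % of |z|, signs kept; d = 0.30 for reporting),
averaged into a group matrix, and decomposed by maximizing signed modularity

    Q = 1/(2w⁺+2w⁻) Σ_ij [A_ij − (s_i⁺s_j⁺/2w⁺ − s_i⁻s_j⁻/2w⁻)] δ(c_i, c_j)

with a multi-restart greedy/fast/tabu search. Global topology (clustering C,
path length L, assortativity A, small-worldness σ = (C/C_rand)/(L/L_rand)) is
referenced to shuffled-weight null ensembles; node roles use degree,
betweenness, within-module degree z and participation coefficient
PC = 1 − Σ_s (κ_is/k_i)². See `docs/methods.md` for every convention and
default.

## Worked example

Run the end-to-end pipeline on a synthetic group-1 style cohort (12 subjects,
5 sessions × 220 volumes, TR 2.2 s) and recover the planted modules:

```python
import painnet as pn

cfg = pn.RunConfig(preset="group1", n_subjects=12, seed=202, run_contrast=False)
res = pn.run_pipeline(cfg)
s = res.summary
print(s["module_sizes"], round(s["Q"], 3), round(s["sigma"], 2),
      s["ground_truth_recovery"])
```

prints

```
[14, 12, 4, 4] 0.548 5.69 {'nmi': 1.0, 'exact_match_after_relabel': True}
```

— the four planted modules (sensorimotor 14, medial fronto-parietal 12,
lateral fronto-parietal 4, limbic 4) recovered exactly (normalized mutual
information 1.0 against ground truth), with signed modularity Q = 0.548 and a
small-world coefficient well above 1 at 30 % link density. The same run is
available stepwise as numbered scripts:

```bash
python analysis/01_simulate_cohort.py    # cohort + example session TSVs
python analysis/02_connectivity.py       # weighted Fisher-z matrices
python analysis/03_graph_metrics.py      # C/L/Q/A/σ across densities 0.10–0.50
python analysis/04_modules_hubs.py       # partition, hub table, link stats
python analysis/05_condition_contrast.py # paired pain-vs-audio contrast
```

`05` shows the planted condition differences: the A1 interhemispheric edge is
significantly stronger under audio (Δz = −0.58), while dozens of
sensorimotor edges are stronger under pain. A `painnet` CLI wraps the same
stages (`painnet run --preset group1 --synthetic --seed 7 --out out/`;
`simulate`, `connectivity`, `graph`, `modules`, `hubs`, `contrast`, `sweep`);
each run writes a summary JSON plus a SHA-256 manifest, and
`painnet run --out out/ --check` verifies it.

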