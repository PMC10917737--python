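# osaconnect

EEG brain-connectivity analysis for contrasting obstructive sleep apnea
(OSA) with healthy sleep. Obstructive sleep apnea fragments sleep and
alters the functional coupling between cortical regions; its signature in
overnight EEG is a strengthening of slow-wave (delta-band) synchronization
between frontal and occipital derivations. `osaconnect` implements the full
analysis chain for 4-channel polysomnographic EEG (F4-A1, F3-A2, O1-A2,
O2-A1 at 200 Hz) and is aimed at sleep researchers who want a scriptable,
tested alternative to ad-hoc toolbox pipelines:

1. **Preprocessing** — 50 Hz IIR notch and 0.5–35 Hz Butterworth band-pass,
   both zero-phase.
2. **Band separation** — level-5 wavelet packet decomposition (WPD) with the
   Daubechies-4 wavelet splits each 30 s epoch into 32 leaves of 3.125 Hz;
   a Gray-code permutation maps the filter-path leaf order to ascending
   frequency, and leaves are grouped into the clinical bands
   δ 0.5–4, θ 4–8, α 8–13, β 13–30, γ 30–35 Hz by center frequency.
3. **Connectivity** — for each band, the Pearson correlation
   r_ij = cov(|w_i|, |w_j|) / (σ_i σ_j) of the channels' absolute wavelet
   coefficients, per epoch, averaged over epochs, giving a symmetric 4×4
   matrix per subject and band.
4. **Graphs** — edges where r_ij > 0, node degree = number of incident
   edges, export in BrainNet Viewer `.node`/`.edge` text formats.
5. **Statistics** — group min/max positive correlation per band;
   Mann–Whitney–Wilcoxon tests (exact for small tie-free samples, otherwise
   tie-corrected normal approximation) of per-subject band summaries; Welch
   t-maps of node degree.

Because overnight clinical recordings cannot ship with a package, a
synthetic cohort generator produces two groups of 4-channel recordings with
prescribed band-specific inter-channel coupling (Cholesky-mixed band-limited
noise over a 1/f floor), so every stage is verifiable end to end.

## Worked example

```python
from osaconnect import BrainConnectivityModel, generate_cohort, paper_contrast_spec

spec = paper_contrast_spec(n_osa=10, n_healthy=10, duration_s=120, seed=1)
subjects, manifest = generate_cohort(spec)
results = BrainConnectivityModel.from_cohort(subjects).fit()
print(results.summary())
```

```
EEG band connectivity group contrast
==========================================================
subjects: OSA: 10, HEALTHY: 10
wavelet: db4 level 5; epochs of 30 s; edge rule r > 0
----------------------------------------------------------
band    group        min pos r   max pos r
delta   OSA             0.4147      0.6529
delta   HEALTHY         0.0471      0.3506
theta   OSA             0.2190      0.3512
theta   HEALTHY         0.1421      0.2903
alpha   OSA             0.0579      0.2223
alpha   HEALTHY         0.0388      0.1996
beta    OSA             0.1292      0.2051
beta    HEALTHY         0.1278      0.1941
----------------------------------------------------------
Mann-Whitney on per-subject mean_pos_r (OSA vs HEALTHY):
band           U        z           p  method
delta      100.0    3.780   1.083e-05  exact *
theta       96.0    3.477   0.0001299  exact *
alpha       60.0    0.756      0.4813  exact
beta        64.0    1.058       0.315  exact
(* p < 0.05, two-sided, no multiplicity correction)
```

The case-like group was generated with delta coupling drawn from
[0.75, 0.90] against [0.45, 0.65] for the control-like group, all other
bands identical. The fitted contrast shows exactly that structure: the
delta-band positive correlations separate the groups (U = 100 is complete
separation of the 10+10 per-subject means; p ≈ 1e-5), alpha and beta do
not. Absolute-coefficient correlations are attenuated relative to the
generating signal coupling (0.65 max here for couplings up to 0.9), which
is expected — see `docs/methods.md`. Theta picks up part of the delta
contrast because the 3.125 Hz leaves do not align exactly with the 4 Hz
band edge.

Real data enter the same way through `read_edf` / `read_columnar`, or via
the CLI:

```bash
osaconnect synth --preset paper_contrast --n-osa 10 --n-healthy 10 \
    --duration 300 --seed 42 --out cohort/
osaconnect run --config run.yaml
osaconnect report --in osaconnect_out/
```

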