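# distexp

Simulation and analysis pipeline for EEG studies of **expectation-dependent
distractor suppression** in visual search.

## The scientific problem

In additional-singleton search, a salient distractor slows target search —
but less so when it appears at a location where distractors are frequent
(statistical learning of a *high-probability distractor location*), and less
so again when its features (here: the spatial frequency of a Gabor) are
predictable within a block. The paradigm this package models has six display
locations on a circle; the distractor appears at one high-probability
location on 70% of distractor-present trials, and target/distractor spatial
frequencies are either fixed ("Dp"/"Tp") or variable ("Dv"/"Tv") within a
block, giving conditions such as *DpTp identical*, *DpTp unique* and
*DpTv unique*.

The EEG signatures of interest are:

* **anticipatory alpha lateralization** — hemispheric asymmetry of 8–12 Hz
  power relative to the high-probability location before search onset,
  quantified by the index (P_contra − P_ipsi)/(P_contra + P_ipsi);
* **time-resolved decoding** of target/distractor spatial frequency from all
  64 channels (per-timepoint shrinkage LDA, balanced 10-fold CV, macro
  one-vs-rest AUC with 0.5 = chance), including *cross-class* decoding
  (train on distractor frequency, test on target-only trials) to ask whether
  target and distractor expectations share a neural code;
* **lateralized ERPs** — the N2pc (contralateral negativity, attentional
  selection) and the Pd (contralateral positivity, active suppression),
  measured as contra−ipsi difference waves over O1/O2, PO3/PO4, PO7/PO8
  with data-driven peak ± 40 ms component windows.

Group inference uses repeated-measures ANOVA with Greenhouse–Geisser
correction, paired t-tests with Cohen's d, and cluster-based sign-flip
permutation tests (1024 permutations) over time and time×frequency.

Because the original recordings are an external deposit, the package ships a
**synthetic-data generator** (`distexp.synth`) that reproduces the design
exactly (block structure, 70% allocation, distractor-absent trials) and
injects controllable ground-truth effects — ex-Gaussian RT benefits,
lateralized alpha, N2pc/Pd deflections, class-specific topographies, EMG
bursts, HEOG steps — so every stage of the analysis chain can be validated
against a known answer.

## Worked example

```python
import distexp as dx

cfg = dx.SimConfig(seed=2, experiment=2, n_subjects=1,
                   blocks_per_condition=3, n_sessions=1, sfreq=128,
                   noise_white_sd=0.2, noise_pink_sd=0.2, alpha_base_amp=0.0,
                   pattern_amp_evoked=3.0, pattern_amp_anticipatory=2.0)
table = dx.simulate_rts(dx.generate_design(cfg, 0), cfg)
epochs, truth = dx.simulate_epochs(table, cfg)

prepared = dx.prepare_decoding_epochs(epochs).crop(-750, 550)
result = dx.time_resolved_cv_decode(prepared, "target_sf", k=10, seed=0)
print(dx.window_average_auc(result, (100, 400)))
print(dx.window_average_auc(result, (-500, -250)))
```

prints (rounded)

```
{'DpTp_identical': 0.915, 'DpTp_unique': 0.915, 'DpTv_unique': 0.899}
{'DpTp_identical': 0.518, 'DpTp_unique': 0.994, 'DpTv_unique': 0.626}
```

Post-onset, the injected spatial-frequency topographies are decodable in
every condition (AUC ≈ 0.9 at this signal-to-noise ratio). Before search
onset, *DpTp identical* sits at chance (no anticipatory code), *DpTp
unique* decodes almost perfectly (the generator's anticipatory target code
is specific to that condition), and *DpTv unique* lands in between: its
anticipatory code is the *distractor's* frequency, which rules out one of
the three classes for the target and therefore carries partial target
information.

The same chain is available from the shell:

```bash
distexp run --seed 7 --config config.yaml --out bundle/
distexp simulate --experiment 2 --subjects 24 --seed 7 --out bundle/
```

writing per-subject trial tables (CSV), epoch containers (flat float32
`.dat` + JSON sidecar) and per-stage CSV/JSON results with a provenance log.

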