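# domfinger

Molecular fingerprinting of bacterially produced dissolved organic
matter (DOM): a tested, reusable Python pipeline for asking whether
bottom-up control (what substrate a heterotroph grows on) and top-down
control (lytic viral infection) leave distinguishable molecular imprints
in the DOM a culture releases.

The package is aimed at chemical oceanographers and microbial ecologists
working with ultrahigh-resolution mass spectrometry of DOM. It covers
the full desk-side analysis chain:

* **Formula assignment** — CHNOS molecular formulas for negative-mode
  FT-ICR MS peak lists ([M-H]- ions) under a ppm tolerance with
  chemical-plausibility windows; the candidate search is exhaustively
  complete with respect to the configured bounds.
* **Molecular indices** — H/C, O/C, double bond equivalents
  (DBE = 1 + C - H/2 + N/2), DBE/C, the modified aromaticity index
  AImod = (1 + C - 0.5 O - S - 0.5(N + H)) / (C - 0.5 O - N - S)
  (clamped to 0 when undefined), elemental classes (CHO/CHON/CHOS/CHONS),
  heteroatom species labels ("O7", "N2O", "NOS"), and intensity-weighted
  per-sample summaries.
* **Inter-sample rank classification** — common formulas ranked by
  relative intensity in each sample; each formula classed by the
  sampling day of its best rank as *preformed* (Day 0 dominant, consumed
  later), *intermediated* (mid-incubation dominant, transient) or
  *remaining* (final-day dominant, produced or undegradable), with
  treatment-consistent unique sets, species count tables, and a
  presence/absence comparison across exudate / mechanical-lysate /
  viral-lysate DOM.
* **Community statistics** — Bray-Curtis dissimilarity, ANOSIM with a
  permutation p-value (R = (r̄_between - r̄_within)/(M/2)), SVD-based
  PCA, Wilcoxon rank-sum (exact for small samples), Pearson/Spearman,
  and per-formula Spearman screening against fluorescence component
  scores at a 95% confidence limit.
* **EEM PARAFAC** — non-negative trilinear decomposition of
  excitation-emission fluorescence stacks by alternating least squares
  with exact NNLS row updates, Tucker-congruence recovery diagnostics,
  and component Ex/Em maxima.
* **Synthetic data** — a first-class generator producing formula
  libraries with latent lability classes, peak tables with treatment x
  time structure, 4-component EEMs, and logistic growth with
  substrate-dependent DOC drawdown, so every stage is testable against
  known ground truth without instrument data.

## Worked example

Classify the lability of formulas in a synthetic five-substrate
incubation and compare the classes against the generator's latent truth:

```bash
python examples/03_rank_classification.py
```

```
common-set intensity coverage per treatment: ['98.7%', '98.2%', '99.0%', '99.5%', '99.3%']
unique preformed    :  237 formulas (99.6% match their latent class)
unique intermediated:  119 formulas (99.2% match their latent class)
unique remaining    :  166 formulas (89.8% match their latent class)
...
formulas found in exactly one DOM-release arm: {'exudate': 8, 'mechanical': 9, 'viral': 36}
```

The common formulas carry ~99% of each sample's signal (comfortably
over the 80% the method assumes), the rank classes recover the latent
decaying/transient/accumulating populations, and only the viral lysate
contributes a large set of arm-unique formulas — the N- and S-rich
saturated species that viral lysis injects.

The other examples each demonstrate one capability with a short printout:
`01_simulate_and_assign.py` (closed-loop formula recovery, ~99% at
0.3 ppm mass error), `02_molecular_indices.py` (DBE/AImod on familiar
molecules), `04_community_stats.py` (ANOSIM by treatment R ≈ 0.8,
p = 0.001; growth-vs-DOC correlation), `05_eem_parafac.py` (4-component
recovery at SNR 20 with congruence ≈ 0.999), `06_full_pipeline.py`
(one-command run writing all tables plus a checksummed manifest).

A thin CLI wraps the same functions:

```bash
domfinger simulate --n-formulas 400 --seed 7 --out scratch/peaks
domfinger assign --peaks scratch/peaks --out scratch/assigned.csv
domfinger run --config demo.yaml
```

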