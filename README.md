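# ffcmargin

Fast field-cycling (FFC) ¹H-NMR relaxometry toolkit for assessing tumour
margins in small breast-tissue specimens excised during breast-conserving
surgery.

## The problem and the method

When a breast tumour is removed, the surgeon needs to know — ideally within
minutes — whether the resection margin still contains malignant cells.
FFC-NMR relaxometry measures the proton longitudinal relaxation rate
R₁ = 1/T₁ of a small tissue specimen as a function of the applied magnetic
field (0.02–1 MHz proton Larmor frequency). The resulting R₁ dispersion
curve — the NMRD profile — separates tissue types: adipose-rich healthy
tissue shows uniformly high R₁ with weak field dependence, while tumour
tissue shows lower R₁ with much stronger dispersion.

Two scalar quantifiers condense a profile:

* **Ratio** = R₁(0.02 MHz) / R₁(1 MHz) — high in tumour-rich tissue;
* **2R₁** = R₁(0.39 MHz) + R₁(1 MHz) (s⁻¹) — high in healthy, fat-rich tissue.

Specimens are classified **positive** (tumour-containing) or **negative**
(healthy) by a sequential two-criteria protocol with fixed cut-offs:

1. measure R₁ at 0.02 and 1 MHz and compute the Ratio;
2. Ratio > 2.19 → positive; Ratio < 1.95 → negative;
3. for borderline specimens (1.95 ≤ Ratio ≤ 2.19), acquire R₁ at 0.39 MHz
   and decide by 2R₁: ≤ 24.0 s⁻¹ → positive, > 24.0 s⁻¹ → negative.

The reversed order (2R₁ first, borderline band 24.0–26.5 s⁻¹) is also
implemented. On the original 104-specimen cohort this protocol reaches 92%
sensitivity and 85% specificity, with both quantifiers scoring a ROC AUC of
0.95.

The package covers the whole chain: synthetic cohort generation (no public
specimen data exist), mono-exponential T₁ fitting of pre-polarized decay
curves, NMRD profile assembly with reproducibility statistics and outlier
fencing, quantifier computation, ROC/cut-off analysis, and the sequential
classifier — also exposed as a scikit-learn estimator
(`SequentialCutoffClassifier`) that composes with sklearn model selection.

## Worked example

Run the full simulated pipeline — 104 specimens (40 healthy H, 43 mixed M,
21 tumour T), six-field acquisition with 32 log-spaced delays per field,
fitting, quantification and sequential classification:

```python
import ffcmargin as fm

report = fm.run_pipeline(fm.PipelineConfig(seed=42, outdir="demo"))
print(report["rates"], report["auc"], report["second_criterion_used"])
```

prints (abridged):

```
{'sensitivity': 0.8125, 'specificity': 0.725, 'accuracy': 0.7788...}
{'ratio': 0.8602, 'two_r1': 0.9336}
8
```

i.e. on this synthetic cohort the protocol classified 52 of 64
tumour-containing specimens and 29 of 40 healthy specimens correctly, with 8
borderline specimens referred to the second criterion. Sensitivity and
specificity are below the figures of the original cohort because the
simulated mixed class deliberately spans the full range of tumour fractions,
including many nearly-healthy specimens (see `docs/methods.md`). All
intermediate tables (decay curves, fits, profiles, quantifiers, decisions)
are written as CSV next to `report.json`.

The same pipeline is available from the shell:

```bash
ffcmargin pipeline --seed 42 --out demo/
ffcmargin simulate --seed 7 --out run/ --n-h 7 --n-m 7 --n-t 6
ffcmargin fit --curves run/decay_curves.csv --out run/fits.csv --profiles-out run/profiles.csv
ffcmargin quantify --profiles run/profiles.csv --out run/quantifiers.csv
ffcmargin classify --quantifiers run/quantifiers.csv --out run/decisions.csv
ffcmargin evaluate --decisions run/decisions.csv --samples run/samples.csv --out run/eval.json
```

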