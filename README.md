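# pgp-lungdisp

Analysis toolkit for transporter-dependent pulmonary drug disposition:
does P-glycoprotein (P-gp) in the lung epithelium limit the absorption of an
airway-dosed substrate, and can that be predicted from the molecule's
physico-chemical profile alone?

The package implements, as tested reusable components, the quantitative chain
used to answer that question for an 18-member panel of P-gp substrates studied
in isolated perfused lungs and intestinal segments from Mdr1a/1b(-/-) knockout
mice and wild-type controls:

* **IPML absorption kinetics** (`ipml_kinetics`) — serial-sampling-corrected
  cumulative absorption from a recirculating perfusate reservoir, nonlinear
  fits of the one-compartment accumulating model
  `%dose(t) = 100·F·(1 − e^(−Ka·t))`, trapezoid AUC₀₋₃₀, lung-retention mass
  balance, and the mannitol barrier-integrity QC rule.
* **Membrane affinity** (`membrane_affinity`) — LogK^IAM from immobilised
  artificial membrane chromatography, `log₁₀((T_r − T₀)/T₀)` with retention
  extrapolated to 100 % water, and multi-lamellar liposome vesicle (MLV)
  partitioning `(C₀ − C_s)/C₀`.
* **Intestinal permeability** (`ussing_permeability`) — apparent permeability
  `Papp = (dM/dt)/(A·C₀)` from Ussing-chamber serosal accumulation with the
  same sampling correction, TEER integrity filters, and knockout:wild-type
  (KO:WT) fold-changes.
* **Transporter kinetics** (`atpase_kinetics`) — Michaelis–Menten `K_m`/`V_max`
  fits to membrane ATPase activation curves and non-reactive flagging.
* **Comparative statistics** (`comparative_stats`) — unpaired t-tests, Pearson
  and Spearman correlations (exact permutation p at small n), rank-impact
  tables and group fold-change summaries.
* **OPLS-DA QSAR classifier** (`oplsda_qsar`) — a from-scratch orthogonal PLS
  discriminant analysis on 13 computed descriptors that separates substrates
  whose pulmonary absorption is P-gp-limited (Group B) from those unaffected
  (Group A), with unit-variance scaling, orthogonal-component deflation,
  cross-validated Q², and prediction for external compounds.
* **Synthetic data** (`synthetic_data`) — seeded generators that are exact
  inverse pairs of each analysis stage, so every estimator is testable without
  any experimental download.

The three compound tables the analysis runs on (descriptors, membrane
affinity, intestinal Papp for all 18 substrates) ship as versioned CSV
fixtures under `pgp_lungdisp/data/`.

## Worked example

```python
from pgp_lungdisp import load_descriptor_table, load_assay_table
from pgp_lungdisp.oplsda_qsar import fit_oplsda
from pgp_lungdisp.comparative_stats import pearson

table1 = load_descriptor_table("table1")   # 18 compounds x 13 descriptors
table2 = load_assay_table("table2", "iam_mlv")

model = fit_oplsda(table1)                 # defaults: 1 orthogonal comp, 7-fold CV
print(model.r2y, model.q2, model.misclassified_names)
# 0.6454187101535488 0.16688671350663886 ('Acrivastine',)

r = pearson(table2["logk_iam"], table2["mlv_partitioning"])
print(round(r.coefficient, 3), round(r.p_value, 6))
# 0.765 0.000215
```

The classifier separates the two substrate groups with a single training
outlier, acrivastine: its descriptors place it among the less-polar Group B
compounds, yet its lung absorption behaves as Group A.  The two independent
membrane-affinity assays agree strongly (Pearson r = 0.765), and descriptors
loading on the Group-A side of the model are exactly the polarity-linked ones
(Abraham acidity/basicity, polar surface area, hydrogen-bond counts).

The same pipeline is available from the shell:

```text
$ pgp-lungdisp reproduce-paper --out repro
report written to repro/report.json
OPLS-DA: R2Y=0.645 Q2=0.167 misclassified=['Acrivastine']
```

Model fit statistics depend on reporting conventions that differ between
chemometrics packages; `fit_oplsda(..., cv_scheme="fixed_orthogonal")` and
`n_orth=0` reproduce the alternative conventions (Q² = 0.51/0.53, R²Y = 0.59).
See `docs/methods.md` for the full discussion.

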