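# riversem

Causal modelling of stream macroinvertebrate communities under
spatiotemporal confounding.

Environmental impact studies on rivers face a stubborn problem: community
composition changes along the stream and across seasons for entirely natural
reasons, so the effect of a wastewater discharge is confounded with distance
and time. `riversem` implements a graph-theoretic structural equation
modelling workflow that makes the confounding explicit and testable. The
user encodes their causal assumptions as a directed acyclic graph (DAG) over
variables such as `time`, `distance`, a binary `effluent` indicator
(upstream = 1, downstream = 0 relative to the discharge point), discharge
loads, nutrient concentrations, and the community itself. Arrows are direct
causal claims; *missing* arrows are independence claims, and those are what
the package tests.

## What it computes

- **Causal graphs** (`riversem.causal_graph`): validated diagrams with
  directed and bidirected arrows (a bidirected arrow `a <-> b` stands for a
  latent common cause, e.g. treatment-plant operation driving several
  discharge loads). d-separation is decided by moralized-ancestral-graph
  reachability. The **basis set** contains one d-separation statement
  `X des Y | pa(X) ∪ pa(Y)` per non-adjacent pair, and its size obeys
  `V(V−1)/2 − A` for `V` variables and `A` adjacent pairs.
- **Ordination** (`riversem.ordination`): Bray–Curtis dissimilarity of
  square-root-transformed abundances, classical PCoA (Gower centring of
  `−½D²`), and distance-based redundancy analysis (dbRDA) with a
  `condition` block — PCO scores are residualised on the conditioning
  design before being projected on the predictors, with a reduced-model
  permutation test for the pseudo-F statistic.
- **Axis diagnostics** (`riversem.axis_diagnostics`): four methods for
  flagging nontrivial PCO axes — broken stick, bootstrap eigenvalue
  confidence intervals, a column-permutation null envelope, and
  percent-of-remaining-variance scree data — plus a consensus rule.
- **Piecewise SEM** (`riversem.sem_pipeline`): one structural equation per
  child node (OLS for environmental variables, dbRDA for the community
  node), nested-F and conditioned-dbRDA tests for every basis-set
  statement, and Fisher's C
  (`C = −2 Σ ln pᵢ`, chi-square with `2k` df) as the global test. Accepted
  models support do-operator **intervention prediction**: arrows into
  intervened nodes are cut, their values fixed, and expected values
  propagated through the fitted equations in topological order.
- **Spatial diagnostics** (`riversem.spatial_diagnostics`): a Mantel
  correlogram over stream-distance classes, checking the independence
  assumption behind the permutation tests.
- **Biotic indices** (`riversem.biotic_indices`): Shannon diversity, EPT
  richness and abundance, SIGNAL scores (user-supplied grade tables), and
  axis–index association tests for interpreting ordination axes.
- **Synthetic river** (`riversem.synthetic_river`): a generator with a known
  causal diagram — seasonal and downstream trends, a latent plant-operation
  variable behind two correlated discharge loads, an exponentially
  attenuating nutrient plume below the outfall, and taxa responding
  log-linearly to the nutrient and distance gradients. Ground truth for
  every stage.

## Worked example

```python
import riversem as rs
from riversem.synthetic_river import SyntheticRiverConfig, generate, true_formulas

site, community, diagram = generate(SyntheticRiverConfig(seed=4))
ev = rs.evaluate_model(diagram, site, community=community,
                       formulas=true_formulas(), n_permutations=199, seed=4)
print(ev.to_text())
```

```
Model evaluation (alpha = 0.05)
----------------------------------------------
  time des distance | {}  [nested_F]  stat=0  p=1
  time des effluent | distance  [nested_F]  stat=0  p=1
  time des load1 | {}  [nested_F]  stat=0.001692  p=0.9672
  ...
  load2 des nutrient | distance, effluent, load1, time  [nested_F]  stat=0.1206  p=0.7289
  load2 des COMMUNITY | distance, nutrient  [conditioned_dbrda]  stat=0.8507  p=0.665
----------------------------------------------
Fisher's C = 17.1919, df = 26, p = 0.9032
Causal structure consistent with the data at alpha = 0.05.
```

Each line is one missing-arrow claim: pairs of environmental variables get a
nested-F test (does adding the variable improve the regression of the
response on the conditioning set?), statements involving the community get a
conditioned dbRDA permutation test. Here all 13 local tests are
non-significant and Fisher's C (p = 0.90) accepts the composite hypothesis,
so the diagram may be read causally and used for intervention prediction:

```python
eqs = [rs.fit_equation(e, site, community=community, seed=4)
       for e in rs.derive_structural_equations(diagram, formulas=true_formulas())]
from riversem.sem_pipeline import predict_intervention
from riversem.synthetic_river import derived_features
pred = predict_intervention(eqs, diagram, {"load1": 0.5}, site,
                            derived=derived_features(SyntheticRiverConfig(seed=4)))
```

```
mean nutrient, observed:      1.4969
mean nutrient, do(load1=0.5): 1.3789
mean |PCO1 shift|:            0.0570
```

Fixing the discharge load at 0.5 (about half its mean) lowers the predicted
mean nutrient concentration and shifts the community's position on the
first PCO axis accordingly.

The same workflow is available from the shell:

```bash
riversem simulate --seed 4 --out sim/
riversem ordinate  --community sim/community.csv --out ord/
riversem diagnose  --community sim/community.csv --seed 4 --out diag/
riversem evaluate  --community sim/community.csv --site-table sim/site_table.csv \
                   --diagram sim/diagram.txt --seed 4 --out eval/
```

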