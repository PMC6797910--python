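# convscan

Detection of convergently adaptive amino-acid sites associated with a
**continuous** environmental trait (habitat temperature, or depth on a log10
scale), on a fixed species phylogeny.

Comparative transcriptomic datasets — e.g. metabolic enzyme alignments from
marine invertebrates sampled across depth and temperature gradients — pose a
recurring question: which alignment columns changed *convergently* every
time a lineage colonised the deep (or the cold)?  `convscan` answers it with
a profile-change-with-one-change (PCOC-style) model comparison extended to
continuous traits, plus a simulation bootstrap that turns per-site posterior
probabilities into calls with a controlled confidence level.

## Method

1. **Trait reconstruction.**  The trait x is reconstructed at every internal
   node under Brownian motion; the estimates are the GLS/ML values computed
   by a two-pass message scheme on the tree.
2. **Convergent scenarios.**  Node values are binned (default widths 1.75 °C
   or 0.2 log10 m); a candidate cutoff is placed at every interior bin
   boundary.  Each cutoff binarises the tree: nodes on the "greater" side
   are *convergent* (orientation inverted if the root would be convergent,
   so the root is always ancestral).  Transition branches are the
   ancestral→convergent cut edges.  Scenarios are deduplicated and must
   carry ≥ 5 independent transitions, guarding against phylogenetic
   pseudoreplication.
3. **Site scoring.**  Each site evolves under one of K amino-acid frequency
   profiles π (a CAT-style mixture).  The per-profile process is F81-type,
   q_ij = β·π_j with β = 1/(1 − Σ_k π_k²), so P_ij(t) = e^{−βt}δ_ij +
   (1 − e^{−βt})π_j in closed form.  For every column, Felsenstein pruning
   gives the null likelihood (one profile everywhere, maximised over K
   profiles) and the PCOC likelihood (convergent branches under a second
   profile π_C, transition-branch child states drawn from π_C, maximised
   over ordered profile pairs).  With equal model priors,
   PP = 1 / (1 + exp(logL_null − logL_PCOC)); the maximum PP across all
   scenarios is reported per site.  Gapped taxa are removed by per-column
   tree pruning.
4. **Bootstrap calibration.**  For each site with PP ≥ 0.5, 1000 null
   columns (ML ancestral profile with Dirichlet noise) and 1000 convergent
   columns (ML pair, transitions per the best scenario) are simulated on the
   site's pruned tree and rescored.  The (1−α) quantile of null PPs and the
   β quantile of convergent PPs (α = β = 0.05 at 95% confidence) bound the
   adaptive / non-adaptive / unresolved regions.
5. **Structural context.**  Downstream statistics relate calls to predicted
   structure: rank-based inverse-normal ("ordered quantile") transformation
   of the B-factor profile, two-way Type III ANOVA on depth/temperature
   adaptiveness, and exact conditional r×c contingency tests of secondary
   structure and solvent exposure composition, with expected counts from
   the predicted non-adaptive sites.

## Worked example

Simulate a discovery experiment end to end from the shell (all inputs are
generated; nothing is downloaded):

```sh
python - <<'EOF'
import numpy as np, convscan as cs
from convscan.tree import balanced_tree

tree = balanced_tree(6, 0.3)                    # 64 tips
tips = tree.tip_labels()
deep = set(tips[0:4]) | set(tips[8:12]) | set(tips[16:18]) \
     | set(tips[24:26]) | set(tips[32:34]) | {tips[48], tips[56]}
traits = cs.TraitTable({t: (10.0 if t in deep else 0.0) for t in tips})
values = cs.reconstruct_bm(tree, traits)
config = cs.AnalysisConfig(bin_width=2.0, n_sims=200, seed=1)
scens = cs.enumerate_scenarios(tree, values, config)
print("scenarios:", [(s.id, s.n_transitions) for s in scens])

true = next(s for s in scens if s.n_transitions == 7)
profiles = cs.load_profiles("c10")
aln, truth = cs.simulate_dataset(tree, true, 100, 400, profiles,
                                 [("hydrophobic", "charged")],
                                 np.random.default_rng(1))
report = cs.scan_alignment(aln, tree, scens, profiles, config)
report = cs.calibrate_report(report, aln, tree, scens, profiles, config)
calls = np.array([r.call for r in report])
kinds = truth["kind"].to_numpy()
print("sensitivity:", (calls[kinds == "convergent"] == "adaptive").mean())
print("null adaptive rate:", (calls[kinds == "null"] == "adaptive").mean())
EOF
```

which prints

```
scenarios: [('c2.0000', 13), ('c4.0000', 6), ('c6.0000', 7), ('c8.0000', 12)]
sensitivity: 0.92
null adaptive rate: 0.0025
```

Four distinct binarisations of the trait survive the ≥5-transition filter;
the 7-transition scenario is the planted one.  92% of the 100 planted
profile-shift sites are recovered as adaptive at 95% bootstrap confidence,
and only 0.25% of the 400 null sites are falsely called adaptive.

The same pipeline is exposed as a CLI
(`convscan scenarios | simulate | detect | bootstrap | structstats`); run
any subcommand with `--help` for the file formats.

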