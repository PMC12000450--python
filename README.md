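# ibd-diseasome

Disease co-occurrence networks and community-robustness analysis of
**extraintestinal manifestations (EIM)** and **associated immune disorders
(AID)** in inflammatory bowel disease (IBD).

IBD — Crohn's disease (CD) and ulcerative colitis (UC) — is a systemic
condition: many patients accumulate immune-mediated disease outside the
gut (arthropathies, uveitis, psoriasis, thromboembolic events, depression
and anxiety, …). Administrative health records encode this as streams of
dated ICD-10 diagnoses, which can be turned into a *diseasome*: a network
whose nodes are diagnosis codes and whose edges connect codes carried by
the same patients. This package implements that analysis chain end to end
for epidemiologists and network-medicine researchers working with
encounter-level data:

1. **Cohort extraction** — the two-year administrative case definition
   (≥ 2 hospitalizations OR ≥ 4 physician claims OR ≥ 2 ambulatory
   contacts with an IBD code inside a 730-day window), plus CD/UC/IBDU
   subtype assignment and age/sex strata.
2. **Frequency tables** — per-organ-system patient counts, 3-decimal
   percents, and CD-vs-UC Pearson chi-square comparisons with Yates
   continuity correction.
3. **Co-occurrence graph** — node weight *n* = unique patients per code
   (display size √n × 0.3 + 2.5), edge weight *m* = unique co-carrying
   patients (display width m × 0.01), with per-edge temporal direction
   counts from first-diagnosis dates, and the usual display filters.
4. **Community detection** — Louvain maximization of weighted
   Newman–Girvan modularity
   `Q = (1/2W) Σ_ij [w_ij − k_i k_j/(2W)] δ(c_i, c_j)`,
   implemented from scratch with the node visit order derived entirely
   from the edge input order.
5. **Robustness evaluation** — matched Dice–Sørensen overlap between
   partitions (optimal bipartite community matching), edge-shuffle and
   disjoint-half patient-sampling experiments, quartile-restricted
   scoring, a uniform random-assignment null with SEM over trials, and
   one-sided Welch tests of real vs. null.

Patient-level registry data of this kind are not redistributable, so the
package includes a synthetic-EHR generator with planted community
structure and full ground truth; every downstream stage is validated
against it. See `docs/methods.md` for the models, conventions and their
rationale.

## Worked example

```python
from ibd_diseasome import (
    SimulationConfig, generate_cohort, build_cohort, CaseDefinition,
    build_graph, louvain,
)
from ibd_diseasome.robustness import (
    shuffle_profile, split_profile, random_null, welch_one_sided,
)

config = SimulationConfig(n_patients=2000, seed=7)   # 4 planted communities
records, truth = generate_cohort(config)
cohort = build_cohort(records, CaseDefinition(),
                      sex=truth.patient_sex, birth_date=truth.patient_birth_date)

graph = build_graph(records, cohort, "IBD")
partition = louvain(graph, edge_order=None)          # alphabetical edge order

shuffle = shuffle_profile(graph, n_runs=12, seed=101)
split = split_profile(records, cohort, n_trials=8, seed=101)
null = random_null(len(graph.nodes), partition.n_communities, 1000, seed=101)
```

prints (via the obvious `print` statements):

```
cohort: {'UC': 744, 'CD': 915, 'IBDU': 160, 'excluded': 181}
graph: 110 nodes, 5717 edges
louvain: 4 communities, Q = 0.4575
shuffle overlap: 1.000 ± 0.000
split overlap:   0.911 ± 0.023
random null:     0.326 ± 0.001
split vs null, one-sided Welch p = 2.09e-08
```

Reading: the 181 excluded patients are exactly the simulated non-cases
(the case definition has sensitivity 1 and no false positives on
noise-free synthetic streams, by construction). Louvain recovers the 4
planted code communities; detected communities are perfectly stable under
edge-order shuffling (overlap 1.0), highly stable under disjoint
patient-half resampling (0.911), and both sit far above the matched
overlap of randomly assigned communities (0.326 for 110 codes in 4
communities), with a one-sided Welch p ≈ 2×10⁻⁸.

## Command line

Each stage is also a CLI subcommand (`simulate`, `cohort`, `freq`,
`graph`, `communities`, `robustness`, `export`), and `all` runs the whole
pipeline from a YAML/JSON config, writing records, cohort, frequency
table, GraphML, partition, robustness results, the vis-network node-link
JSON payload and a manifest:

```bash
ibd-diseasome all --seed 7 --outdir out/
```

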