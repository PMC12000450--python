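# Methods

This note documents the models, conventions and design choices behind
`ibd_diseasome`. It is the package's own account of what it computes; every
number mentioned here is produced by the test suite or the scripts, not
asserted from memory.

## Problem setting

Inflammatory bowel disease (IBD — Crohn's disease, CD; ulcerative colitis,
UC) is a systemic condition: a large fraction of patients accumulate
extraintestinal manifestations (EIM) and associated immune disorders (AID)
— arthropathies, uveitis, psoriasis, thromboembolic events, depression and
anxiety, and so on. Given long-format administrative encounter data
(patient id, date, ICD-10 code, encounter type), the package

1. extracts an IBD case cohort with a validated administrative case
   definition,
2. tabulates EIM/AID frequencies by organ system with CD-vs-UC
   comparisons,
3. builds a disease co-occurrence ("diseasome") graph over ICD codes,
4. partitions it into communities with Louvain modularity optimization,
   and
5. quantifies how robust those communities are to the algorithm's order
   sensitivity, to patient resampling, and relative to a random null.

Because patient-level registry data of this kind cannot be redistributed,
the package ships a synthetic-EHR generator with planted ground truth; all
quantitative claims about recovery and robustness are made on that
generator's output.

## Case definition (cohort_builder)

A patient is a case if some 730-day window contains **≥ 2
hospitalizations**, OR **≥ 4 physician claims**, OR **≥ 2 ambulatory-care
contacts**, each clause counted over IBD-coded encounters only (prefixes
K50/K51 by default; ICD-9 555/556 can be added via `CaseDefinition.
ibd_prefixes`). Windows are evaluated by sliding a closed interval of
`window_days` calendar days anchored at each IBD-coded encounter date
(window = `[anchor, anchor + window_days − 1]`); "two years" is fixed at
730 days, ignoring leap days, for determinism. Clauses never pool across
encounter types.

Subtype assignment uses a documented stand-in for the registry's
unpublished scoring system: strict majority of IBD-coded encounter counts
(K50.x → CD, K51.x → UC); ties or mixed streams without a majority → IBDU.
Whether the original algorithm counted raw encounters or distinct service
dates is unknowable from public sources; the rule here is deliberately
simple and exposed in the API.

Age at first encounter is computed from the birth date at the patient's
earliest record (fractional years, floored for stratum assignment); strata
are `<18`, `18–64` (inclusive) and `>64`.

## Frequency layer (frequency_stats)

* Percents are computed in exact decimal arithmetic and rounded
  **half-even to 3 decimals**, matching the tabulation style of the
  registry reports this layer reproduces.
* CD-vs-UC binary comparisons use the Pearson chi-square on the 2×2 table
  **with Yates continuity correction** (toggleable). The correction is the
  convention that reproduces published p-values from their printed counts
  (e.g. 0.0438 and 0.0029 in the regression fixture); the uncorrected
  statistic does not. No multiple-testing adjustment is applied —
  deliberately, to mirror the reporting style being reproduced — so the
  p-value columns must be read accordingly.
* Medians/IQRs use linear-interpolation percentiles.
* Organ-system grouping uses an **ordered** domain map over ICD-10 chapter
  ranges. The IBD index range K50–K51 is listed first (index codes are
  never EIMs); a custom "Cerebrovascular diseases" domain (I60–I69 plus
  the venous thromboembolism block I80–I82) precedes the general
  circulatory chapter. Published tables do not enumerate their exact
  per-domain code membership, so the default map is a best reconstruction
  and is a user-editable JSON/YAML file.
* In frequency tables a patient counts once per domain regardless of code
  multiplicity; denominators are per-disease cohort sizes. Sex-stratified
  rows should use the sex-known subtotal as denominator.

## Co-occurrence graph (cooccurrence_network)

Nodes are ICD codes; node weight *n* is the number of unique patients ever
carrying the code, displayed at size **√n × 0.3 + 2.5**. An undirected
edge joins two codes carried by at least one common patient; edge weight
*m* is the number of unique co-carrying patients, displayed at width
**m × 0.01**. Each co-carrying patient is classified by comparing the
first-diagnosis dates of the two codes (strictly earlier → a-first or
b-first; equal dates → same-day), giving per-edge temporal direction
counts that sum to *m*.

Co-occurrence is lifetime (ever/ever): no window is imposed between the
two first diagnoses. IBD index codes are included as nodes (they anchor
the clusters); codes outside the domain map are dropped. Edges are stored
once per unordered pair with `code_a < code_b` lexicographically.

Display filters mirror an interactive viewer's controls: minimum pair
count (default 1 — a single shared patient suffices), top-N heaviest pairs
(default cap 1000), domain subset, and code truncation. Truncation to
`max_code_length` characters re-aggregates *n* and *m* as unique-patient
counts recomputed from the retained per-(patient, code)
first-diagnosis-date table — summing child counts would double-count
patients carrying several child codes. Isolated nodes are removed after
edge filtering.

## Louvain (community_detection)

Implemented from scratch (the package's core algorithm; the `networkx`
implementation is used only as an independent cross-check in the tests).
Weighted Newman–Girvan modularity at resolution 1:

    Q = (1/2W) Σ_ij [w_ij − k_i k_j / (2W)] δ(c_i, c_j)

with w_ij = m for each edge, k_i the weighted degree and W the total edge
weight. Self-loops (possible after code aggregation) count twice in the
degree, the standard adjacency convention.

Numerical choices:

* **Visit order.** Phase-1 node order is the order of first appearance in
  the supplied edge sequence; aggregated super-nodes inherit the order of
  their earliest member. The edge input order is therefore the *single*
  source of run-to-run variability — exactly the knob the edge-shuffle
  robustness experiment turns. `edge_order=None` means fixed alphabetical
  order; an integer is a shuffle seed; an explicit permutation is used
  verbatim.
* **Move acceptance.** A node moves only for a gain exceeding `1e-12`
  (avoids float ping-pong between equal-gain moves); candidate communities
  are scanned in sorted id order, so ties keep the current community.
* **Termination.** Phases repeat until the modularity gain of a full level
  is below `1e-12`.
* Community ids are densely renumbered by descending community size, ties
  broken by the lexicographically smallest member code; the fixed display
  palette (blue, yellow, green, red, purple, then an overflow palette)
  follows that order.
* Disconnected graphs are handled natively; isolated nodes end as
  singleton communities. An edgeless graph is an error (Q undefined).

On graphs small enough to enumerate every partition, the implementation
attains the exhaustive modularity optimum on disconnected-clique families
and ≥ 0.95× the optimum on random connected graphs (see
`tests/test_louvain.py`).

## Robustness (robustness_eval)

Two partitions are compared by **matched Dice–Sørensen overlap**:
communities are paired by the assignment maximizing total Dice
(`scipy.optimize.linear_sum_assignment`, i.e. optimal, not greedy — greedy
matching is order-dependent and was rejected for reproducibility), the
smaller side padded with empty communities that score 0 against anything
non-empty; the mean over matched pairs (padding included) penalizes
disagreement in community count. Dice of two empty sets is defined as 1;
when overlap is restricted to a code subset, communities emptied by the
restriction are dropped before matching (an all-empty side is an error).

* **Edge-shuffle experiment** — Louvain re-run on the full graph with
  independently shuffled edge orders; consecutive run pairs scored
  (n_runs − 1 scores).
* **Split-sample experiment** — per trial, the case patients are halved at
  random into equal, mutually exclusive sets; a graph is built and Louvain
  run per half with *fixed alphabetical* edge order (isolating sampling
  variability from algorithmic variability); the two partitions are
  scored. Trials whose half-graph is edgeless are skipped and logged.
* **Random null** — per trial, two independent uniform assignments of the
  code set to k communities, scored the same way. Uniform (rather than
  size-preserving) assignment is the most literal reading of "random
  assignment to communities"; with optimally matched pairing the expected
  base overlap is 1/k either way, plus a positive matching bonus, so the
  null mean is strictly above 1/k. At the published IBD network scale
  (467 codes, 5 communities, 1000 trials) the package computes a null mean
  of ≈ 0.243 with SEM ≈ 3×10⁻⁴ (`scripts/acceptance.py` recomputes this
  from scratch). A published value of 0.232 ± 0.001 under an unspecified
  matching/null-size convention is compatible within the stated tolerance
  band but suggests the original used a slightly different convention
  (e.g. greedy matching); the package's convention is fixed and documented
  here.
* **Quantile restriction** — overlap recomputed over only the codes whose
  population frequency falls in a given quartile. Boundaries are
  linear-interpolation percentiles; intervals are half-open below the top
  quartile (Q0 = [min, p25), …, Q3 = [p75, max]), so with all-equal
  frequencies every code lands in Q3.
* **Real-vs-null comparison** — one-sided Welch t-test (Satterthwaite df)
  for H1: mean(real) > mean(null), with exact handling of zero-variance
  samples (both constant: p = 0.5/0/1 by the sign of the difference).

All experiments consume one master seed; trial *t* uses
`numpy.random.default_rng([seed, t])`, so any trial is reproducible in
isolation.

## Synthetic-EHR generator (synthetic_ehr)

The generator emulates the statistical structure the analysis assumes:

* **Disease mix** defaults to CD 0.47 / UC 0.35 / IBDU 0.08 / non-case
  0.10 — the CD:UC:IBDU ratio of a large administrative registry (about
  0.52 : 0.39 : 0.09 among cases) with a 10% non-case fraction to exercise
  the classifier's reject path.
* **Encounter streams.** Each IBD-labelled patient receives a stream
  satisfying exactly one randomly chosen clause of the case definition
  (dates confined to a 730-day window inside the 2002–2020 observation
  span); CD/UC streams draw codes only from their own K50.x/K51.x family,
  IBDU streams alternate K50.9/K51.9 evenly so no majority exists. With
  `case_noise > 0` that fraction of IBD-labelled patients instead receives
  a sub-threshold stream (1 hospitalization + ≤ 2 claims) violating all
  three clauses; non-case patients carry at most one IBD claim. Sensitivity
  and specificity of the classifier on noise-free output are therefore 1
  by construction — the corresponding tests validate the implementation,
  not the case definition's field performance.
* **Planted code structure.** K communities × c codes per community,
  synthesized over realistic chapter letters (F, M, N, I, J, G, E, H, D,
  L, R) with two-digit blocks placed inside mapped organ-system ranges so
  chapter grouping is exercisable; community blocks are contiguous in code
  index but span chapters, so "cluster" and "ICD hierarchy" colorings
  differ. Each patient is assigned one community uniformly and carries
  each of its codes with probability `p_within` (default 0.3) and each
  other code with `p_between` (default 0.01) — the classic planted
  partition regime, strongly recoverable at the default 2000 patients.
* **Temporal ordering.** Within each community, consecutive code pairs are
  designated (earlier, later) pairs; for a patient carrying both, the
  first-diagnosis dates are ordered accordingly with probability
  `temporal_bias` (default 0.8 — a clear but imperfect ordering signal;
  0.5 would mean none) and strictly reversed otherwise, with equal dates
  nudged apart by one day. Other first dates are uniform over the span.
* Repeat encounters for an already-diagnosed code occur with probability
  0.2 at a later date, to exercise first-diagnosis deduplication.

What the generator does **not** emulate: realistic marginal prevalences
per organ system, age/sex-dependent coding, utilization intensity,
medication exposure, coding errors, or correlated comorbidity beyond the
single planted block structure. Passing tests therefore demonstrate that
the pipeline recovers structure that is present and calibrated — not that
real registry data contain such structure.

## Problem sizes

The default study conditions — and the sizes used throughout the tests and
scripts — are: 2000 patients, 4 planted communities × 25 codes,
p_within = 0.3, p_between = 0.01; 12 shuffle runs, 8 split trials, and
1000 null trials (467 codes × 5 communities for the null at the published
network scale). A full pipeline run at these sizes completes in a few
seconds on one CPU.

## Known limitations

* The subtype rule and the per-domain code membership are documented
  reconstructions, not the registry's originals.
* The null model and community matching convention are fixed choices among
  several defensible ones (see above); sensitivity to greedy matching is
  available behind `match_partitions` + manual pairing but not wired into
  the experiments.
* Louvain is a heuristic: no optimality guarantee beyond the small-graph
  oracle tests; Leiden-style refinement and multi-resolution scans are out
  of scope.
* The browser renderer itself is out of scope; the package emits the
  node-link payload (vis-network dialect) only, without layout
  coordinates.
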