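# Methods

## Scope and model class

`bnsens` studies discrete Bayesian networks used as single-disorder
diagnostic classifiers: one categorical class variable (the diagnosis) and
categorical finding variables, each quantified by a conditional probability
table (CPT).  Inference is exact; continuous variables, approximate
inference and Noisy-OR/MAX parameterizations are out of scope.  Structures
are inputs (generated or read from BIF); the package does not learn graph
structure.

## Noise operators

All three operators act per CPT column (one conditional distribution) in
base-10 log-odds space, `Lo(p) = log10(p/(1−p))`, which keeps perturbed
values inside (0, 1) and makes the noise magnitude σ scale-free.

* **Symmetric**: every entry independently maps to
  `Lo⁻¹[Lo(p) + Normal(0, σ)]`.  For binary columns this preserves the sum
  automatically (the transform is antisymmetric about 0.5); for multi-state
  columns the vector is renormalized to sum to 1 afterwards.  Both entries of
  a binary column are transformed independently and then renormalized — the
  same uniform rule as for multi-state columns.
* **Overconfidence**: the smallest entry `p_S` becomes
  `Lo⁻¹[Lo(p_S) − |Normal(0, σ)|]` and the removed mass is added to the
  largest entry.  The sum is preserved exactly, no renormalization; entropy
  cannot increase.  Emulates experts whose estimates drift toward 0 and 1.
* **Underconfidence**: mirror image — the largest entry is shrunk the same
  way and the mass is given to the smallest entry, flattening the column.
  At large σ the modified entries can swap rank; entropy is guaranteed
  non-decreasing only while the rank order is preserved.

Numerical conventions:

* Ties: `p_S` is the first index attaining the minimum; `p_L` is the first
  index attaining the maximum among the remaining indices.  This always
  picks two distinct states (uniform columns included) and is deterministic.
* Entries exactly 0 or 1 are ±∞ fixed points of the log-odds transform and
  pass through every operator unchanged (no epsilon clamping).  Deterministic
  CPT columns are therefore immune to this noise model — a property users
  should be aware of, not a bug.
* A zero draw is implemented as an exact identity (including skipping the
  symmetric renormalization), so σ = 0 reproduces the input bitwise.
* Draw order is fixed — variables in declared order, columns row-major over
  declared parent state orders, entries in state order — so perturbation is
  reproducible given a seed, and the vectorized whole-table path consumes
  the identical draw stream as the per-distribution operators.
* Draws are independent per parameter, per column, per leave-one-out
  iteration; nothing is shared across columns of one CPT.

## Evaluation protocol

Leave-one-out over a dataset of n records: CPTs are re-estimated from the
remaining n − 1 records by relative frequency with a Dirichlet pseudocount
(default 1, Laplace; 0 gives maximum likelihood with a uniform fallback for
configurations never observed), the target CPTs are perturbed with fresh
draws, and the class of the held-out record is predicted as the argmax of
its exact posterior given the observed findings.  Ties in the argmax go to
the earliest declared state.  Accuracy is the fraction of correct argmax
diagnoses (so accuracy × n is always an integer count); the mean posterior
assigned to the true diagnosis is reported alongside.

Default pseudocount 1 is a deliberate choice: the noise model cannot move a
zero probability, and pure maximum likelihood produces zero columns that
make some leave-one-out evidence impossible.  Evidence of probability zero
raises inside inference; the evaluation loop catches it, scores the case as
incorrect and flags it (never silently drops or falls back to uniform — a
silent fallback would corrupt the accuracy statistics).

Evidence: by default every non-class variable is observed (datasets are
complete after imputation); an explicit evidence list supports
partial-evidence studies.  Under complete evidence the class posterior
factorizes so that only the CPTs of the class node and of its children
matter — every other factor is a positive constant that cancels in
normalization.  Two consequences worth stating plainly:

1. Noise outside {class} ∪ children(class) is provably inert in the
   complete-evidence protocol.  The complement-of-blanket condition of the
   blanket experiment is therefore exactly flat here.  Empirical studies
   that report accuracy loss from non-blanket noise must be using partial
   evidence (or multi-disorder aggregates); the package supports the
   partial-evidence variant through the generic evaluation path so both
   regimes can be examined, and deliberately does not guess which protocol
   any particular published curve used.
2. The leave-one-out hot path exploits the same locality: for each record it
   materializes and perturbs only the CPT rows selected by that record's
   parent configurations.  Unused rows would receive independent draws that
   cannot influence the result, so row-local perturbation reproduces the
   full perturb-everything protocol exactly in distribution and
   deterministically per seed.  The generic path (estimate, perturb the
   whole network, run variable elimination) remains the reference
   implementation for partial evidence, and the two paths agree exactly at
   σ = 0.

Inference is variable elimination with a min-degree heuristic on the
moralized evidence-reduced graph, ties broken by variable name — exact and
deterministic at the desk scales used here (≤ 70 nodes).

Seeds: every sweep cell (σ index, noise type, replicate) derives its own
generator from the base seed via a seed sequence keyed on the cell
coordinates, so cells are independent and order-of-execution invariant.
The condition label (blanket / complement / all, or the semantic tag) is
deliberately excluded from the key, so conditions with identical target
sets produce identical results — this is what makes the blanket condition
reproduce the all-nodes condition exactly on naive-Bayes-like structures.

In the blanket experiment the "Markov blanket" condition targets
MB(class) ∪ {class}: the blanket region including the class node itself.
This keeps the three conditions partition-consistent (blanket ∪ complement
= all variables) and makes the blanket condition coincide with the
all-nodes condition whenever every node lies in the class's blanket region.
The `markov_blanket()` operation itself keeps the conventional definition
(parents ∪ children ∪ co-parents, target excluded).

## Synthetic gold standards

The generator emulates single-disorder diagnostic models at the scale of
the common public medical datasets (8–70 nodes, 2–20 diagnoses, a few
hundred to a couple of thousand records):

* The class node is a root with a Dirichlet-drawn prior, allowing the
  imbalanced prevalences typical of disease panels.
* Findings are tagged history / physical / lab.  Each is a direct child of
  the class with probability `direct_child_fraction` (default 1.0, a
  naive-Bayes core); the rest attach to an earlier finding, keeping the
  class an ancestor of everything while shrinking its Markov blanket —
  the structural regime that differentiates the blanket experiment.
  Additional finding→finding edges appear with `extra_edge_density`
  (default 0.1, capped at 3 parents per node), mirroring TAN/ANB-like
  learned structures.
* CPT columns are symmetric Dirichlet draws.  `concentration` (default 0.5)
  is the difficulty dial: lower values give extreme, highly diagnostic
  columns and a higher Bayes-optimal ceiling.  Laboratory columns are
  sharpened by raising entries to `lab_boost` (default 2.0) and
  renormalizing — lab tests are modeled as the most diagnostic findings.
* Records are ancestral samples; cells are blanked completely at random at
  `missing_rate` (default 0.05, matching the "under 5% missing" regime of
  typical public medical datasets) and imputed with state 0 of each finding,
  designated the normal/absent state.

What the generator does **not** emulate: real datasets' label noise and
model misspecification (records here really are drawn from the gold
standard), systematically missing-not-at-random values, continuous
measurements and their discretization, and multi-disorder panels (the
accuracy metric requires a single class variable; a multi-disorder
aggregate is not defined here).  Passing tests on synthetic ensembles
therefore demonstrate the internal consistency and the qualitative noise
phenomena, not performance claims about any real clinical model.

`bayes_optimal_accuracy` gives the argmax-classifier ceiling of a gold
standard: exact by enumeration of the joint (up to 4 × 10⁶ cells, in log
space for stability), otherwise Monte Carlo with a reported binomial
standard error.

## Study conditions and problem sizes

The ensemble replication (in `bnsens.benchmark` and used by both the test
suite and `scripts/acceptance.py`) runs 20 generated networks of 10–20
nodes with 2–6 diagnoses, 300–500 records each, σ ∈ {0, 0.1, 0.5, 1, 1.5,
2}, all three noise types, 5 replicates per cell.  The average-posterior
protocol uses one 15-node network with 300 records and a σ grid up to 3.0.
These sizes were chosen to match the public-dataset scale the generator
emulates while keeping the full suite reproducible on a laptop.

## Known limitations

* Single class variable; no multi-disorder accuracy aggregate.
* Complete-evidence locality means Experiment-2/3 style contrasts are only
  informative about CPTs in the class's blanket region unless partial
  evidence is used (see above).
* Deterministic (0/1) parameters are invisible to the noise model.
* The BIF dialect implemented is the common 0.15 core (discrete variables,
  `table` and per-configuration rows, `property` lines); exotic extensions
  are rejected with line-numbered parse errors rather than guessed at.
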