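# Methods

This note documents the models, defaults, and numerical choices behind
`crowdgene`, and what the simulation-based tests do and do not establish.

## Wrapper scoring

A hand of 1–5 genes is scored by the cross-validated accuracy of a
decision-tree classifier restricted to exactly those genes — a wrapper
feature-set evaluation. Defaults: 5-fold stratified cross-validation, one
repeat, fold assignment a fixed function of the CV seed, and accuracy
pooled as total correct / total predictions across folds. Stratified CV
requires `n_folds` not to exceed the smaller class; unstratified folds
containing a single training class are an error rather than silently
rescored.

The tree is a deterministic binary CART: axis-aligned threshold splits
minimising weighted Gini impurity, candidate thresholds at midpoints
between consecutive distinct sorted values, defaults `max_depth=3`,
`min_leaf=5`. Determinism is contractual because the score defines game
outcomes and the opponent's policy: among equally impure splits the
lowest feature index wins, then the lowest threshold; leaf-prediction
ties go to class 0. An off-the-shelf tree learner does not pin down these
tie-breaks, which is why the CART is implemented here (it is
oracle-checked against exhaustive enumeration of all depth-1 splits, and
cross-checked against scikit-learn on unambiguous fixtures). Scores are
permutation-invariant in the hand (features are canonically ordered
before fitting) and cached by (dataset fingerprint, CV config, gene set),
which makes crowd simulation tractable.

A perfectly separating gene scores exactly 1.0; constant hands fall back
to the majority-class rate. Note that adding a strong gene to a hand is
*not* guaranteed to raise a cross-validated score — only the exact
statements above are asserted.

## Game and opponent

Boards hold 25 distinct genes; players alternate single picks, human
first, five picks each; the final hands are scored and the higher wrapper
score wins. The automated opponent is greedy one-step lookahead: it takes
the remaining gene maximising the wrapper score of its current hand plus
that gene, breaking exact score ties uniformly at random. Equal final
scores default to an opponent win (`bot_wins_ties=True`, configurable):
the game's reward is only defined for wins and losses, and a tie
conservatively withholds the win.

Board generation has two modes. `generate_boards` samples genes without
replacement under optional per-gene weights (uniform by default).
`generate_balanced_boards` is a coverage-balancing semirandom
composition — each board takes the currently least-covered genes with
random tie-breaking — used where every gene in the pool must be seen by
the crowd (appearance counts stay within one of each other). Boards are
ordered by difficulty: the wrapper score of the full 25-gene set,
renumbered so the most predictive (easiest) board is number 1, ties
keeping their original order.

## Simulated crowd

Players carry registration-survey answers (degree, biologist?, cancer
knowledge?). Cohorts are pure functions of the answers: *expert* = PhD or
MD **and** declared cancer knowledge; *inexperienced* = no advanced
degree, no cancer knowledge, not a biologist; everything else — including
any missing answer — is *other*. Missing answers are generated only
within the *other* stratum (default rate 5.4%, matching typical survey
nonresponse), because missingness anywhere else would silently reclassify
the player and break the requested cohort mix.

Each agent selects among remaining board genes with probability
∝ exp(β·relevance(g)): β = 0 is uniform random play; large β approaches a
greedy oracle on the latent relevance score. Games per player follow a
discrete power law (Zipf, default exponent 1.8, capped at 718). Lifecycle
rules: any open board may be chosen (uniformly, among boards the player
has not won); a board closes once the closure threshold of distinct
players (default 11) has finished a game on it; winning a board bars
replay; a loser replays the same board with probability `replay_prob`
(default 0.3 — the replay *option* is a rule of the game, the rate is a
generator choice). All randomness flows from the crowd seed.

What the generator emulates: cohort structure, knowledge-driven
selection, heavy-tailed engagement, and the board lifecycle. What it does
not: learning over time, churn, registration dynamics, board preference
by difficulty, or adversarial behaviour beyond the replay rule. Passing
recovery tests therefore show that the aggregation statistic extracts a
knowledge signal the crowd actually carries — not that any particular
human crowd carries one.

## Aggregation statistic and null

Only each player's first finished game per board is counted (the
first-five-cards filter). For each counted game, every board gene gains
one occurrence O and every human-selected gene one selection S, so
ΣS = 5 × games and ΣO = 25 × games — asserted after every tally. Genes on
multiple boards pool their counts. F = S/O; genes with O = 0 are not
reported.

The null distribution of S given O is simulated, not assumed. In
`symmetric_random` mode both players pick uniformly at random, so by
symmetry the tracked gene lands in the human's final hand with
probability hand/board = 0.2 per game, independently across games; each
replicate simulates O such games. This makes the closed-form
Binomial(O, 0.2) upper tail an *independent oracle* (`exact_binomial_p`),
and the empirical null is required to match it within Monte-Carlo error.
In `vs_bot` mode each game is played out in full — random human against
the greedy opponent on a reference dataset — which shifts selection
probabilities away from 0.2 because the opponent systematically removes
predictive genes; it is proportionally expensive and intended for small
replicate counts. It exists because a purely symmetric null cannot
reproduce every published behaviour of such systems: dynamics with a
non-random opponent push low-F tail probabilities off the binomial
values.

Empirical P values use the floored convention max(r, 1)/n_iter, where r
counts replicates with S_null ≥ S: with the default 10,000 iterations the
smallest reportable P is 10⁻⁴, and S = 0 always yields P = 1. Ranked sets
sort by (P ascending, F descending, O descending, symbol) and retain
P ≤ alpha (default .001). Null tables round-trip through a per-O
histogram TSV with a metadata header.

## Evaluation

Overlap and enrichment are one-tailed hypergeometric (overrepresentation
only), with reference sets and catalog terms intersected with the
declared background — the analogue of restricting to genes that appeared
in at least one game — before testing. Only terms overlapping the query
(k ≥ 1) are tested; skipped terms would contribute P = 1 and only dilute
the Benjamini–Hochberg correction, which is applied across all tested
terms (via statsmodels, behind `bh_adjust`).

Classifier benchmarks restrict train and test data to a gene set
(dropping genes absent from either side and reporting the usable count),
standardise per gene on the training data only, and fit a linear SVM with
C = 1 (no settings are published for this step; these are the plainest
defaults). `compare_gene_sets` pools the provided train/test samples and
re-splits them stratified once per seed at the original test fraction,
evaluating every gene set on the identical split — a paired design; with
a fixed split a linear SVM is deterministic, so re-splitting is what
gives the per-seed variation.

## Problem sizes and numerical choices

Simulation-heavy tests run at desk scale, chosen as the smallest sizes at
which the tested signal is identifiable: the system-level
parameter-recovery check uses a 100-gene pool with 10 planted genes
(between-class shift 2 within-class SDs, 60 samples), 15
coverage-balanced boards, and a 70-player crowd (70% knowledgeable
agents, β = 8; 30% uniform), closure at 11, over 10 seeds. Uniform board
sampling is deliberately *not* used there: it leaves each planted gene a
~10% chance of never appearing, and no aggregation method can rank a gene
the crowd never saw. Null tables in tests use 10⁴–10⁵ iterations;
empirical-vs-exact comparisons allow 3 Monte-Carlo standard errors plus
the 1/n_iter floor, and skip tail points below Monte-Carlo resolution
(exact P < 50/n_iter).

Degenerate inputs are errors, not warnings: duplicate gene symbols,
non-binary or missing labels, empty sample intersections, hands with
unknown genes, single-class scoring, out-of-turn moves, weights
insufficient to fill a board, P values outside [0, 1].

## Known limitations

- The wrapper score depends on the CV protocol and tree settings; other
  protocols will reorder borderline hands and hence opponent choices.
- The greedy opponent is the simplest policy consistent with the game's
  rules; stronger lookahead would change game records and tallies built
  on top of them.
- `vs_bot` null simulation is exact in structure but slow; its replicate
  counts are necessarily small, so its P values are coarse.
- Individual genes are ranked, not gene *sets*: interactions visible only
  jointly (e.g. XOR-like pairs) are invisible to F.
- Ties in final scores, and the opponent's true policy in the deployed
  game, are underdetermined by the published rules; both are explicit,
  configurable defaults here.
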