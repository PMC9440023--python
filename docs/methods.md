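# Methods

`delphikit` implements the statistical core of a multi-round Delphi
consultation used to build hierarchical indicator systems — here, the
evaluation index system for a rat third-degree-burn animal model, whose
published two-round tables ship as packaged fixtures.

## The consultation model

A panel of experts anonymously scores every active indicator of a
three-tier hierarchy (primary / secondary / tertiary) on a bounded
integer importance scale. Alongside each score the expert reports a
familiarity self-rating (six ordinal levels) and a self-rated judgment
basis on four dimensions: practical experience, theoretical analysis,
understanding of peers, and insight. After each round the indicators
are screened, the hierarchy is revised through a logged edit trail, and
the surviving indicators are rescored.

### Engagement

The *positive coefficient* of a round is the questionnaire recovery
rate, 100·returned/distributed, with ≥ 70% conventionally read as good
engagement. In the packaged study the rates are 100% (15/15) and
86.67% (13/15).

### Authority

For expert *i* on indicator *j*:

* the familiarity coefficient **Cs** maps the self-rating to
  {1, 0.8, 0.6, 0.4, 0.2, 0};
* the judgment coefficient **Ca** sums, over the four bases, an impact
  coefficient drawn from a 3-band × 4-basis matrix (default rows sum to
  0.6 / 0.8 / 1.0 for uniformly low / mid / high self-ratings);
* the authority coefficient is **Cr = (Ca + Cs)/2**, with Cr ≥ 0.7
  treated as acceptable reliability.

Per-indicator Cs and Ca are unweighted means over responding experts.
The published tables report per-indicator values without stating the
aggregation; the unweighted mean is the only aggregation consistent
with "average familiarity of the consultants", and it exactly
reproduces the published strict band partitions of Cr
((29, 22, 3) and (8, 36, 2) for >0.75 / 0.5–0.75 / <0.5).
A panel-level Cr (mean of per-indicator Cr) is reported in
`summary.json` as an informational quantity only: the aggregation
behind the published panel values (0.73/0.67) is unstated, so no exact
comparison is meaningful.

### Concentration

Per indicator *j* with m_j respondents: mean importance **Mj**,
standard deviation, coefficient of variation **Vj = sd/Mj**, and
full-score frequency **Kj = m′_j/m_j** (fraction awarding the maximum
score). The sd denominator is n−1 by default and configurable; the
published tables cannot discriminate the choice without raw scores.

### Coordination

Tie-corrected Kendall's W over the m × n score matrix:

    W = 12S / (m²(n³ − n) − m·ΣTᵢ),   Tᵢ = Σ over tie groups (t³ − t)

with ranks assigned descending (most important = rank 1; W is invariant
to this convention, which is fixed only so intermediate output is
reproducible). Significance uses χ² = m(n−1)W on n−1 df; an optional
permutation test (per-expert score shuffles) is available for very
small panels. W > 0.4 flags good coordination, W > 0.5 that
consultation can stop; the stopping rule is reported, never enforced.
W is computed over all active indicators jointly by default (per-tier
is a configuration choice; nothing in the source settles it).

### Boundary-value screening

Across indicators, each criterion gets a retention boundary: mean − sd
for Mj and Kj (keep strictly above) and mean + sd for Vj (keep strictly
below). Comparisons are strict — a value exactly at the boundary fails
its criterion, following the "higher than the boundary value" wording
of the method; as a corollary, a degenerate group with identical
statistics fails everywhere (every value sits at its boundary), which
the tests document. Failing all three criteria deletes an indicator
outright; failing one or two defers it to expert review; review
outcomes arrive as a structured edit log (delete / keep / rename /
move / add), and deleting a statistically retained indicator is allowed
but flagged `expert-override`. The published round-1 revision itself
contains such an override ("model construction time consumption",
mean 7.33, removed on expert advice), which is why the pipeline treats
expert review as a mandatory logged stage and never asserts that the
statistical screen alone reproduces the published deletion set.
Boundary grouping is global across active indicators by default.

## Rounds and reproducibility

`run_round` executes engagement → authority → concentration →
coordination → screening and writes `stats.csv`, `screening.csv`,
`summary.json`. Outputs are byte-identical across reruns: indicators
are ordered by hierarchy position then id, display rounding is fixed
(Mj/sd/Vj and Kj% at 2 dp, Cs/Ca/Cr at 3 dp, ties half-up, matching
the published tables), and nothing is random. `advance_hierarchy`
replays an edit log deterministically; replaying the packaged round-1
log on the 8/16/54 hierarchy yields exactly the published 8/14/46
system. The pipeline supports any number of rounds.

## The packaged fixtures

The two published per-indicator tables are transcribed verbatim,
including three known printing faults, which are enumerated as
constants in `delphikit.datasets` rather than silently corrected:

* the round-1 Kj% column duplicates the Mj column (typesetting fault);
  Kj is always recomputed from raw scores and that column is never used;
* round-2 "Subcutaneous injury" prints Kj% = 28.46, not k/13 for any
  integer k (evidently 38.46);
* four Vj cells and one Cr cell differ from sd/Mj resp. (Ca+Cs)/2
  recomputed from the printed inputs by slightly more than half a
  printed ulp — the source computed them from unrounded raw statistics.
  Tests pin these rows to the a-priori error-propagation bound of the
  printed 2-dp/3-dp inputs (for Vj: 0.005·(1+Vj)/Mj + 0.005; for Cr:
  0.001) and hold every other row to half an ulp.

## Synthetic panels

The generator emulates the study design: 15 experts (7 clinical
medicine / 8 animal research, 5/8/2 across the <15 / 15–30 / >30-year
experience bands, 10 associate professors / 5 professors), an
8/16/54 hierarchy, and 2 round-2 dropouts (recovery 86.67%). Scores
are C_ij = clip(round(μ_j + ε), scale) with ε ~ N(0, σ), independent
across experts and indicators; σ defaults to 1.5, which reproduces the
mid-range of the published per-indicator SDs (≈0.8–3.5 after clipping).
When μ is not supplied it is drawn uniformly on [3, 9.5] — a panel
whose indicators are mostly plausible but spread, as a screened
literature-derived pool is. Familiarity and judgment ratings are
i.i.d. categorical draws whose default marginals put most experts in
the familiar/high bands. A shifted-binomial noise option produces
heavy integer ties for exercising the W tie correction, and an optional
full-score affinity adds a bonus probability of an outright maximum
score for near-top μ (default off), since Gaussian noise under-produces
full marks at high μ.

What the generator does **not** model: expert anchoring or
confirmation-bias dynamics across rounds (round-2 noise is independent,
not contracted toward round-1 feedback), correlation between an
expert's familiarity and the accuracy of their scores, and systematic
scorer severity. Passing recovery tests therefore show that the
statistics and screening recover a known ground truth under honest
independent noise — not that a real panel's behavioural dynamics are
captured.

## Numerical choices and problem sizes

* Half-up decimal rounding is used only for display/output; all
  statistics are computed and compared at full precision.
* Degenerate inputs: zero respondents excludes an indicator with a
  warning; a zero mean makes Vj undefined (NaN + warning); an all-tied
  score matrix defines W = 0; single-respondent indicators get sd = 0.
* Monte-Carlo checks in the test-suite use study-sized panels
  (15 × 54) with 100–200 replicates and fixed seed lists, sizes chosen
  so the full suite runs in well under a minute while the binomial
  tolerances still bind.
* The published panel-level W (0.435/0.530), panel Cr (0.73/0.67) and
  the exact 11-indicator deletion set cannot be recomputed without the
  unpublished raw per-expert scores; they are replaced by property
  checks (oracle agreement for tie-corrected W, monotone degradation of
  E[W] in σ, ground-truth recovery, screening invariants).

## Known limitations

* Dispositions depend on the printed-precision statistics when
  screening is re-run from a rounded `stats.csv`; run screening inside
  `run_round` (full precision) for authoritative decisions.
* The boundary method is the only screening rule implemented; other
  Delphi consensus conventions (median/IQR rules) are out of scope.
* Free-text expert comments are represented only as the structured
  edit log; no text is interpreted.
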