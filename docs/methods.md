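# Methods

## The coding language

A manipulative action is an `object, action, location` triple. Units
are written innermost/topmost cup first and base (contact) cup last, so
`12` is the unit made by inserting cup 1 into cup 2, and `12N3` moves
that unit into cup 3. Ranks run 1 (smallest) to n (largest) and are
contiguous within a trial.

Verbs: `N` combines and releases; `H` combines without releasing the
hand (a *put*); `D` detaches the object from the premade unit named in
the location; `X` covers every other manipulation, with optional
subtypes `XM` mouth, `XR` replace on the floor, `XV` reverse, `XB`
bang. Only `N` is printed in the published notation; the `H`/`D`/`X`
letters are this package's convention for the remaining categories.
The floor location is written `f`. Parsing is case-insensitive and
ignores whitespace around `/`.

Two dialects exist. The compact dialect writes one digit per cup and is
only well defined for ranks ≤ 9; the extended dialect separates ranks
with `.` (`1.2N3`). Because a dot-less token such as `3N12` is
ambiguous between the two readings, dialect selection is by declared
cup count: a `.` anywhere, or `n_cups > 9`, selects the extended
dialect, and the renderer applies the same rule, so `parse(render(e),
n) == e` whenever the declared count matches.

### Canonicalization

Published coding practice does not fix whether the location token names
the whole receiving unit or only its top cup. `canonicalize()` accepts
both: it replays the sequence, rewrites every location token to the
full unit actually targeted (for `D`, to the full remainder of the
source structure), and flags each rewrite. Object tokens must name a
top-contiguous segment of one structure — grabbing a buried cup is
rejected, since a coder would have recorded a disassembly first.

## The cup world

A structure is an ordered stack of cups, base first. Ranks are
distinct, so each adjacency is fully determined: the upper cup is
either smaller (*IN*, nested) or larger (*ON*, piled). The model is
deliberately minimal:

* **Contact rule.** When a unit is combined onto a structure, only the
  receiving structure's top cup decides nest vs pile; a dropped cup
  settles on whatever is uppermost, with no re-sorting or telescoping
  of intermediate sizes. Continuous geometry (diameters in cm, grasp
  kinematics, gravity) is out of scope.
* **Rigid composite moves.** Units containing ON adjacencies still move
  as one object; their internal relations are preserved.
* **Replace-on-floor** (`XR`) of a nested cup detaches it like `D`;
  all other `X` subtypes are state-neutral.

Derived quantities: *complete seriation* is one structure holding all n
cups with every adjacency IN (stack n, n−1, …, 1); *maximum nesting* is
the longest contiguous run of IN adjacencies anywhere (non-contiguous
ranks count — 5 holding 3 holding 1 is a 3-cup nesting — and a bare
singleton scores 1, so a score of 2 means "at least one insertion");
*hierarchical level* of a structure is its number of combinatory
relations, i.e. cups − 1; *minimum moves* to seriate n cups is n − 1
(each combine merges exactly two structures), verified against an
exhaustive breadth-first search of the reachable state graph for n ≤ 4
in the test suite and acceptance script.

## Classification

Each action is categorized on its own against the pre-action state —
per-action categorization, not a judgment of the whole trial. The rule
table is first-match: `H` → put, `D` → disassemble, `X` → other; for
`N`, the object's contact cup is compared with the location's top cup
(nest if smaller, pile if larger; equality cannot occur), the object's
size (single cup vs unit) selects the row, and the location's unit
status (single cup vs unit) selects the column:

nest, single object → pairing (single location) / pot (unit location);
nest, unit object → subassembly (single location) / unit–unit (unit
location); pile → pile (single object) / pile sub (unit object),
regardless of the location's unit status.

A put is labeled put regardless of what the combination would have been
on release. The label is a pure function of (pre-state, event), so
replays are exactly reproducible.

## Summaries

Per trial: per-category counts and percentages of all manipulative
actions in the trial; success (complete seriation of the final state);
maximum nesting of the final state; hierarchical level of the final
largest structure. Zero-event trials report all percentages as 0 with
an explicit `undefined_pcts` flag rather than being dropped.

Per participant, the analyzed trial is the chronologically last among
those with that participant's maximum cup count (the cup-count key
dominates recency; chronology uses the `date` column when present, list
order otherwise). Human participants are binned into six inclusive
age classes in completed months: 12–17, 18–23, 24–29, 30–35, 36–41,
42–48. Other species are pooled.

Group aggregation of percentages is the unweighted mean of member
trials' percentages — the per-participant percentage is the stated unit
of analysis — with pooled-count percentages reported alongside, since
the two differ when trials have unequal lengths and the published
figures cannot disambiguate which was used. The group standard
deviation of manipulations per trial is the sample SD (n−1), reported
as absent for single-trial groups. All arithmetic is unrounded;
presentation rounding is one decimal, half-up.

## The simulator

Each agent holds nonnegative propensity weights over the nine
categories, a size-judgment error probability, and an action budget.
Per step it samples an intended category among those feasible in the
current state, realizes it as a concrete object/location choice, and
emits the event; trials stop at complete seriation (optional) or budget
exhaustion.

Design choices, in decreasing order of consequence:

* **Feasibility fallback.** An infeasible category passes its weight to
  its developmental precursor (pot → pairing, unit–unit → subassembly →
  pairing, pile sub → pile), so a pure-pot agent can make its opening
  pairing. The recorded ground-truth intent is the realized (post-
  fallback) category, and each event also records the per-step
  feasibility-adjusted intent distribution — the target for parameter
  recovery.
* **Size-greedy nest realizations.** Nest intents choose the largest
  fitting object and the tightest receiver (a pot-origin pairing
  instead opens with the two largest cups). A uniform choice over legal
  realizations would let a pure-pot zero-error agent strand itself
  (e.g. pairing 1 into 3 blocks every pot continuation), contradicting
  the minimum-move property that a perfect-size pot policy seriates n
  cups in exactly n − 1 combines. Pile, put, disassemble and other
  realizations are uniform over legal choices.
* **Error model.** With the configured probability, a combine intent's
  size comparison is corrupted: the object lands on a smaller top and
  piles (or, for pile intents, nests), when such a misrealization is
  physically possible. The intent is recorded uncorrupted, so label–
  intent disagreement measures exactly the injected noise; at zero
  error, classifier labels equal intents event for event.
* **Corrective disassembly.** A disassemble intent preferentially
  detaches at the topmost *bad junction* — a pile, or a size gap
  (upper rank < lower rank − 1) that blocks an exact seriation —
  emulating the observed removal of visibly wrong combinations;
  structures without bad junctions split uniformly.
* **Seeding.** Each trial runs on its own stream seeded from
  (cohort seed, group, participant, trial), so cohorts are order-
  independent, embarrassingly parallel and byte-reproducible.

### Default cohort

The default schedule emulates the study design: six child age classes
with 7/10/12/12/12/14 participants (one analyzed trial each) and ten
adult-chimpanzee trials (five simulated individuals, two trials each),
3–10 cups per trial rising with age, per-trial action budgets sampled
from each class's observed manipulation-count envelope (5–37 up to
23–192), and a propensity gradient: pairing-dominant toddlers shifting
toward pot and then subassembly/unit–unit with age, with size-judgment
error falling from 0.30 to 0.01 and off-task (other/put) weight
shrinking. Size-judgment error is additionally scaled per participant
by a uniform draw on [0, 2] (mean 1), giving the within-class skill
heterogeneity visible in the wide published per-class ranges. The
propensity values themselves are this package's choices: raw per-event
data are not deposited, so they were set once to produce a plausible
developmental profile (rising subassembly-family share, success rates
rising from near 0 to ~75%, manipulation counts spanning ~10–170) and
are not fitted to any subject.

### What the generator does and does not emulate

It reproduces the statistical *structure* of coded trials — legal
sequences, feasibility-constrained category mixes, trial-and-error
combine/disassemble loops, success defined as complete seriation, the
published envelopes of cup counts and sequence lengths. It makes no
cognitive claims: there is no learning within or across trials, no
memory, imitation or goal gradient, and agent parameters are not fitted
to any real participant. Tests passing on synthetic cohorts therefore
validate the *pipeline* (parsing, state tracking, classification,
aggregation), not any developmental hypothesis about real children or
apes.

## Numerical and degenerate-input conventions

* Percentages are exact ratios of integers times 100; group means use
  `statistics.mean`; no floating-point accumulation beyond that.
* A single-cup trial's initial state already counts as a complete
  seriation; empty event lists summarize to zero counts with the
  undefined-percentages flag.
* `min_moves(0)`, empty groups, and empty trial lists raise domain
  errors rather than returning sentinels.
* Parser errors carry the token index and text; canonicalization errors
  carry the event index; mid-sequence illegal moves report the state.

## Problem sizes

The test suite and acceptance script use 200-trial recovery cohorts
(nine cups, budget 100, ≈20 000 events), 500 trials per noise level for
the monotonicity check, and BFS verification up to four cups (the
reachable graph grows super-exponentially; n = 4 already has hundreds
of states and fully certifies the closed form's base cases, with the
pot-agent construction certifying attainability up to ten cups).

## Known limitations

* The contact rule ignores cup telescoping: physically, a mid-sized cup
  dropped into a wide stack could slide past a larger cup; here it
  always rests on the top cup.
* Whether original coders permitted moving non-top-contiguous segments
  is unknown; this package forbids it.
* The put category is never sub-labeled by its would-be combination;
  any secondary tally of "intended" puts would need the pre-state,
  which `LabeledEvent.pre_state_digest` preserves.
* Group percentage aggregation offers mean-of-percentages and pooled
  counts; published group figures cannot be used to decide between
  them, so both are emitted.
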