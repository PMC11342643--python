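# Methods

`prltrain` is the computational core of a tele-rehabilitation application for
people with age-related macular degeneration (AMD): a scotoma
self-assessment test on the Amsler grid, eccentric-viewing exercises
projected on a practitioner-chosen peripheral retinal zone (the treatment
area around the preferred retinal locus, PRL), a closed-loop difficulty
controller with a content-based exercise recommender, and a synthetic
patient that closes the loop for testing.  This note describes the models,
the parameters that matter, and the design choices taken where the problem
was genuinely open.

## Grid geometry and visual angle

The conceptual chart is a 10 × 10 cm grid of lines spaced 0.5 cm apart,
viewed at a working distance of 30 cm, with the fixation point at its
centre.  Offsets are converted to visual angle per component as
θ = atan(offset / distance).  One grid square then subtends
atan(0.5/30) = 0.955°, which rounds to the conventional 1° per square; the
per-component arctangent (rather than the 2·atan(s/2d) central-angle form)
was chosen because it keeps the per-square convention additive across the
lattice, and the two forms agree to the printed precision at these scales.
The conventional "whole grid ≈ 20°" figure is the 20-squares-of-1°
convention, not an exact trigonometric claim (the exact value is 18.9°);
the engine documents the convention but asserts only the per-square
rounding.  Axes: x positive rightward, y positive upward; the origin is the
fixation centre.  Cells are indexed (row, col) from the top-left, 0-based.

Screen eligibility: the grid test requires a screen at least as large as
the chart; exercises run on any screen, but stimulus positions and sizes
are kept in absolute centimetres (no rescaling), so the retinal projection
is preserved provided the working distance is kept.

## Self-assessment test

A full test presents 50 red-dot stimuli, each displayed 3 s with 3 s left
to respond before the next — a 300 s schedule.  The stimulus layout is not
dictated by the protocol, so the engine uses stratified random sampling:
the 20 × 20 cell lattice is partitioned into a 5 × 5 block grid and 2
distinct cells are drawn per block (quota spillover handles non-default
grids), then the presentation order is shuffled.  This guarantees
reproducible whole-field coverage from a seed.  Any tap within the
display-plus-response window counts as seen; a reaction time beyond the
window is recorded as missed.

A follow-up test halves the stimulus count (ceiling: 25) and restricts
placement to the *environment of the scotoma*, operationalised as all cells
within Chebyshev distance 2 (configurable) of any previously missed cell,
with the radius expanded automatically if that region cannot hold the
requested number of distinct stimuli.  Its schedule is 150 s, inside the
intended 2–3 minutes.

The scotoma map is strictly per-cell and traceable: a cell is missed or
seen according to the most recent stimulus presented there, and untested
otherwise.  Recency wins on retests because the test exists to track
changes and progression.  The estimator deliberately performs no spatial
interpolation; with 50 stimuli over 400 cells a single test samples 12.5 %
of the field, so a complete map requires pooling several tests (eight
disjoint full tests cover the grid at most).  Passing recovery tests with
the deterministic simulated patient therefore shows correctness of the
mapping rule, not that two tests suffice to survey a real field — they do
not, and the package makes no such claim.

## Exercise engine

The initial catalogue implements the fifteen exercises proposed by the
visual rehabilitator; the revised catalogue applies the user-testing
changes (demonstration not counted as an exercise, touch-anywhere
responses with a 5 s interval for the figure and object exercises,
sequential alternating fixation with voice guidance, target shown at least
twice and at reduced size in the object exercise, the two face exercises
merged, the scene search fixed-dot and compulsorily voice-guided, the two
reading tasks dropped), leaving 11 exercises plus a demonstration.  Image
families are abstract identifiers; rendering, audio and hit-testing
geometry are out of scope (touch-target taps carry a boolean oracle).

Streams are seeded: target slots are drawn uniformly without replacement —
their count is max(min_occurrences, round(n × target_fraction)), default
fraction 0.5 — and filler slots are filled uniformly without immediate
repetition.  Defaults not given by the protocol: 10 events per session,
session duration n × interval unless overridden, alternating fixation
points 4 cm apart symmetric about the centre.  Every event's position is
the treatment-area centre offset from its active fixation point; for
sequential alternating exercises the active point is resolved at scoring
time by the state machine (switch prompted after every missed target).
Scoring: tap in a target window = hit; tap in a non-target window = miss
counted as a false alarm; untapped target = miss; attempts = taps + target
presentations.  False alarms are recorded separately and never folded into
a composite score.  The practitioner-adjustable parameter set is exactly
{inter-stimulus time, stimulus count, stimulus size, session duration}.

## Ability model, difficulty index, and the closed loop

Each exercise lists the skills it requires (fixation stability, eccentric
detection, shape/letter/object/face recognition, fixation switching,
visual search, reading) with weights in [0, 1].  Patient ability per skill
is an exponentially weighted moving average of session success rates,
a′ = (1 − α)a + αs with α = 0.3; reaction times enter only as running
means per skill with a slow/fast flag.  Age and recorded visual
difficulties offset the initial prior only (−0.05 for age ≥ 75, −0.03 per
difficulty, clipped to [0.1, 0.9]).

The difficulty index maps a spec to [0, 1]:

    D = 0.5 · rank/9 + 0.3 / (1 + size_cm) + 0.2 / (1 + interval_s)

where rank is the task-kind order (demonstration < single-fixation figures
< real objects < faces < alternating fixation < scene search < letter
lines) plus the figure-complexity rank (solid < hollow < bold letters <
plain letters).  D is strictly increasing in rank and strictly decreasing
in stimulus size and interval, and the saturating transforms keep it
bounded for any positive parameters.

The recommender is content-based: for each enabled exercise the target
level is the requirement-weighted ability plus a margin δ = 0.1, and the
exercise whose difficulty is closest to its target *from above* is chosen
(closest from below if none lies above; ties break on the lower id),
keeping the task slightly above the current level.  Self-adjustment after
each session: if misses exceed hits, size and interval grow by the step
factor 1.5 (one step easier); if the success rate exceeds the band's upper
edge (0.8), both shrink by the same factor (one step harder); ties and
in-band results hold.  A safety rule makes the no-escalation guarantee
structural: after a session with misses > hits the candidate set is capped
at that session's difficulty index.  Without the cap, a failing session
with success 0.4 can still *raise* a low ability estimate and, through the
margin, escalate difficulty — the cap closes that corner case exactly.

Control-loop design analysis (which fixed the defaults above): a patient
whose hit probability is σ(k(a − D)) has staircase equilibrium where the
probability of a harder step equals that of an easier step; with 5 targets
per session this sits near a per-session success of 0.70, the centre of
the target band [0.6, 0.8].  The step factor 1.5 makes one step ≈ 0.03–0.04
in D, so the loop reaches equilibrium well inside a 10-session burn-in from
the revised catalogue's difficulty range (0.19–0.53).  The rolling success
rate is a 10-session moving mean (≈ 50 targets, binomial s.e. ≈ 0.065).

Compliance is a count: an alert fires iff completed sessions fall short of
the prescribed number in the evaluation window (vacuously no alert for a
zero prescription).

## Synthetic patient

The simulated patient emulates only what the engine needs to be tested in
closed loop: (i) a detection field with probability p_in = 0.05 inside a
localized scotoma (default: a 3 × 3-cell block, i.e. 1.5 × 1.5 cm, in the
upper-right parafoveal field) and p_out = 0.98 outside, optionally blended
linearly over an edge-softness window (default 0, a hard edge); (ii)
exercise hits with logistic probability σ(k(a − D)), true ability a = 0.6
(a patient mid-rehabilitation, reachable by the catalogue's difficulty
range) and slope k = 8 (a reasonably steep psychometric function: ±0.25 of
ability–difficulty margin spans success 0.12–0.88), with a 0.02 false-alarm
probability on fillers; (iii) truncated-normal reaction times (mean 0.9 s,
s.d. 0.3 s, floor 0.2 s, truncated to the response window); and (iv) a
per-session Bernoulli compliance gate.  All responses are reproducible
from the seed.  The simulator has no fixation instability, no learning or
fatigue drift, no spatial correlation in lapses, and no retinal realism:
tests passing against it validate the engine's logic and control
behaviour, not clinical performance.

## Problem sizes and numerical choices

Monte-Carlo checks use 20 seeds with two 50-stimulus tests (scotoma
recovery) or 30-session programs (closed loop) — sizes at which the
binomial/rolling standard errors quoted above make the assertions stable —
and run in seconds.  Divisibility of the grid spacing is checked to 1e-9;
the angle round-trip is exact to 1e-9; difficulty comparisons use a 1e-12
tolerance for tie detection.  Degenerate inputs are defined, not guessed:
empty plans have zero duration, a session with no scoreable targets leaves
the ability model unchanged, the Jaccard of two empty sets is 1, and an
empty enabled-exercise set is an error because enabling exercises is the
practitioner's decision.

## Known limitations

Networking, authentication and the web/mobile interfaces are out of scope;
"upload" is an atomic local export that clears sync-pending flags.
Voice/Talkback settings are carried as inert metadata.  Monocular/binocular
is a recorded label, not a behavioural change.  The per-cell scotoma
estimator does not interpolate between tested cells (see above); a region-
level survey needs several pooled tests, which the follow-up mode is
designed to make cheap.
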