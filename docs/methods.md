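# Methods

## Scope and data model

The package evaluates predicted sperm trajectories against reference
trajectories for one microscopy video. A *detection* is a head-centroid
point `(frame, x, y, label)` in pixel/image coordinates (origin top-left,
y down); a *track* is the frame-ordered sequence of detections sharing a
label. Frame gaps inside a track are legal — the baseline linker's frame
memory produces them — and are never interpolated: path distances are taken
between consecutive *recorded* detections, and elapsed time always uses the
frame span, so a gap widens the denominator without adding fictitious path
length. Labels are opaque strings; `"1"` and `"01"` are distinct, which
avoids silently merging tracks when files mix zero-padded and bare numeric
ids.

Sperm are points, not masks. Segmentation-overlap association (IoU) is
deliberately not offered: the flagellum is pixel-sparse and its labeling
ambiguous, so mask overlap is an unstable pairing signal for sperm. All
association is per-frame, one-to-one, on centroid distance.

## Association

Each frame is matched independently: among ground-truth/prediction pairs
with Euclidean distance ≤ τ (inclusive), the assignment maximizes the
number of matches and, among maximum-cardinality assignments, minimizes
total distance. This is solved as a single Hungarian problem in which
forbidden pairs carry a finite penalty `M = (n + m + 1)·τ`; since any
feasible pair costs at most τ and there are fewer than n+m of them, no
optimal solution ever trades a feasible match away, and penalized
assignments are dropped after solving. Detections are sorted by label
before solving so equal-cost ties resolve identically run to run.

τ defaults to 25 px — the same scale as the baseline linker's search
range — but is a required-to-log parameter: scores at different cutoffs are
not comparable.

## The seven scores

All scores are computed from one `MatchTable` (TP/FN/FP per frame plus the
matched label pairs).

**Graph scores (DET, LNK, TRA).** The track set is viewed as a graph whose
nodes are detections and whose edges join temporally consecutive recorded
detections of one track (gap-spanning edges included). A predicted edge is
*correct* iff both endpoints are matched, to the same reference track, and
those two reference detections are consecutive recorded detections of that
track in the same order. Because matching is one-to-one within each frame,
a correct predicted edge covers exactly one reference edge and no reference
edge can be covered twice. With edit costs `w_FN=10` (add missing node),
`w_FP=1` (delete spurious node), `w_EA=1.5` (add missing edge), `w_ED=1`
(delete spurious edge):

    DET = 1 − min(w_FN·FN + w_FP·FP, w_FN·N) / (w_FN·N)
    LNK = 1 − min(w_EA·FNe + w_ED·FPe, w_EA·E) / (w_EA·E)
    TRA = 1 − min(AOGM, AOGM0) / AOGM0,
          AOGM  = w_FN·FN + w_FP·FP + w_EA·FNe + w_ED·FPe
          AOGM0 = w_FN·N + w_EA·E

The cost is clamped at the build-from-scratch cost AOGM0, so these three
scores live in [0, 1]. Two standard edit operations are structurally absent
here: node *splits* cannot occur under one-to-one point matching, and
edge-semantics changes are vacuous because sperm tracks have no division
events. The weights are configurable for anyone wanting different
conventions.

**TF** is the mean over reference tracks of (longest run of consecutive
recorded detections all matched to one predicted label) / (track length).
Contiguity is required: a track identified by A, briefly lost, and
re-identified by A again does not concatenate its runs.

**MOTA** = 1 − (FN + FP + IDSW)/N. An identity switch is counted when a
matched reference detection's predicted label differs from the predicted
label of that track's *most recent previous* match — switches across gaps
count. MOTA is unbounded below; dense false positives will drive it
negative.

**IDF1** solves a one-to-one assignment between reference and predicted
track identities maximizing total per-frame overlap; with IDTP that
maximum, IDF1 = 2·IDTP/(N + N_pred).

**HOTA** is evaluated at the single association cutoff τ, not averaged over
a threshold sweep — keeping all seven scores on one association was judged
more interpretable than sweeping one of them. DetA = TP/(TP+FN+FP); each
matched pair c with identities (g, p) gets
A(c) = TPA/(TPA+FNA+FPA) where TPA counts matches with the same identity
pair and FNA/FPA the remaining detections of g and p; HOTA = √(DetA·AssA)
with AssA the mean of A(c).

Undefined cases (no reference detections for DET/TRA/MOTA; no reference
edges for LNK, i.e. all-singleton reference; both sets empty for IDF1/HOTA)
raise a typed error; the CLI reports such scores as `null` and exits 4.

## Motion filter

Immotile sperm and debris are easy to track and inflate every score, so an
optional pre-filter removes — identically from reference and prediction —
all tracks whose *span radius* (maximum distance of any detection from the
track's first detection) does not exceed ε, or that hold fewer than
`min_length` detections. The boundary is strict: span exactly ε is removed.
Span is measured from the first detection rather than the path centroid
because it is order-1 computable and directly expresses "extends past a
radius". Defaults ε = 5 px and min_length = 9 detections (≈ 1 s at 9 fps)
are package choices, mandatory to log; no published values exist for them.

## Kinematics

Per track, with calibration `um_per_px` and `fps`:

- VCL = Σ‖consecutive recorded detections‖ · um_per_px / Δt
- VSL = ‖last − first‖ · um_per_px / Δt
- VAP = VCL of the smoothed path

where Δt = (last_frame − first_frame)/fps. The smoothed path is a centered
moving average over recorded detections whose window shrinks symmetrically
at the ends (output i averages inputs i−k…i+k, k = min(half, i, n−1−i)), so
endpoints are preserved, the output has the same frame stamps, and window 1
is the identity. The default window of 5 frames is an explicit package
choice — the smoothing window is a known arbitrary knob in CASA — and is
logged with every output. Averaging is a convex combination, so VAP ≤ VCL
and VSL ≤ VCL always (asserted with 1e-9 slack in the record type).
Velocities are whole-track time averages, matching how CASA distributions
are usually plotted; no sliding-window variant is computed. BCF, ALH, LIN,
STR and motility-class assignment are out of scope.

Histograms use 20 equally spaced bins from 0 to the maximum velocity
observed among *all* samples being compared, so counts are directly
comparable across algorithms. Bins are right-closed (with 0 kept in the
first bin) so integer-valued samples sitting exactly on bin edges fall in
the bin below — this makes `{1..20}` give exactly one count per bin.
Distribution distance is the first Wasserstein distance
(`scipy.stats.wasserstein_distance`); for equal sample sizes it reduces to
the mean absolute difference of sorted samples.

## Baseline detector and linker

The detector reimplements the classic bright-spot localization recipe:
band-pass (Gaussian smoothing at a 1 px noise scale minus a boxcar
background at the diameter scale, clipped at zero), grey-dilation local
maxima with minimum separation of one diameter, iterative center-of-mass
refinement inside a circular mask of radius diameter/2, and rejection of
features with integrated band-passed mass < minmass. Defaults: diameter
11 px, minmass 500. A vectorized boxcar-mass pre-filter (window sum ≥
minmass/2) keeps noise maxima out of the per-peak refinement loop; it can
only discard candidates that could never pass the mass threshold. Exact
numerical agreement with any external particle-tracking library is a
non-goal; the tested contracts are recall 1 and RMS localization error
< 0.2 px on separated rendered spots.

The linker assigns detections to active tracks per frame transition by a
globally optimal Hungarian solve on squared displacement, with pairs beyond
the search range forbidden (same big-M construction as the association
step). This diverges deliberately from the subnet-decomposition heuristics
of common tracking libraries: global optimality is simpler to specify and
test. Unmatched detections open new integer labels in order of first
appearance; a lost track may skip up to `memory` frames (a track last seen
at frame f can be resurrected at f+memory+1 at the latest) and reappears
under its old label with a gap — never with interpolated detections.
Defaults: search range 25 px, memory 3 frames. Candidate tracks are ordered
by (first frame, label) so equal-cost ties favor the senior track.

**Bounding-box correction.** For YOLO-style per-frame annotations, each
box is replaced by the detected centroid that falls inside it when exactly
one does; with zero or multiple interior detections the box center is kept
as the unambiguous fallback. Box membership is inclusive of edges.

## Synthetic scenes and the corruption oracle

The generator states a world rather than tuning one: a 512×512 px field
recorded for 270 frames at 9 fps (the 30 s, 9 fps regime of long-timescale
CASA recordings), populated by default with 18 progressive swimmers
(3–15 px/frame — up to but below the 25 px search range, with 0–4 px
lateral oscillation at 0.5–3 Hz), 6 circling tracks (radius 10–40 px,
0.1–0.4 rad/frame) standing in for hyperactivated motility, 8 immotile
cells (≤ 1 px jitter) and 4 debris points. Oscillation is a sinusoidal
lateral displacement about a straight mean path — the minimal model that
reproduces VCL > VAP > VSL — with no hydrodynamics. Boundaries either
reflect (triangle fold, default) or terminate tracks at first exit.
Closed forms used in tests: a non-oscillating progressive track has
VCL = VSL = VAP = v·fps·um_per_px; a circling track has per-frame chord
2r·sin(ω/2), so VCL = 2r·sin(ω/2)·fps·um_per_px and VSL → 0 over whole
turns. These ranges are chosen for test coverage of the tracking regimes,
not fitted to any particular donor population.

The corruption engine injects four countable error types — isolated
detection deletions (FN), isolated far-from-everything spurious detections
(FP), pairwise label-tail exchanges applied at the co-recorded frame where
the two tracks pass closest (crossover failure), and track fragmentation
under a fresh label (dropout/relabeling) — plus optional localization
noise, Gaussian clipped at 3σ. Events claim a ±1-frame neighborhood on the
tracks they touch (claims travel with exchanged or split tails), so induced
counts are additive: per deletion 1 FN plus 1–2 missing edges (and one
spurious gap-spanning edge if interior); per swap 2 identity switches,
2 missing and 2 spurious edges; per fragment 1 switch and 1 missing edge.
When the set cannot host all requested events, the shortfall is logged
explicitly. The induced-count contract — evaluation recovers the log
exactly — holds when the association cutoff exceeds the clipped noise and
stays below the spurious-point margin (default 50 px), and when distinct
tracks stay separated beyond the cutoff at shared frames; the acceptance
tests construct scenes satisfying these premises.

Rendering draws each detection as an isotropic Gaussian spot (default
amplitude 200, σ 2.5 px) on optionally noisy frames (σ 2.0), which is
sufficient to exercise detector recall, localization, minmass rejection and
the linker end to end. It makes no attempt at phase-contrast halo
artifacts, flagella, or intensity variation between cells — a green
end-to-end test establishes pipeline correctness on clean spot imagery,
not detector robustness on real phase-contrast video.

## Test scaling choices

The rendered-scene checks run on a 640×640 px, 60-frame crowded scene and a
six-lane 50-frame sparse scene rather than full 30 s videos; both complete
in seconds while exhibiting the phenomena under test (fragmentation of fast
movers below the search range; exact recovery on well-separated slow
tracks). The sparse-scene tracks are laid on parallel lanes precisely
because the recovery contract is stated for scenes without path crossings.

## Known limitations

- All reported velocities require a user-supplied μm/px calibration;
  nothing validates it.
- HOTA at a single τ is not numerically comparable to sweep-averaged HOTA
  values from other toolkits.
- The corruption contract is conditional (see above); heavily crowded
  scenes corrupted with large noise can violate its premises, and the log
  then no longer exactly predicts the counts.
- The detector is a clean-room reimplementation; its outputs will differ
  in detail from any specific particle-tracking library even at identical
  parameter values.
- Video containers are not decoded; frames must be supplied as image files
  or arrays.
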