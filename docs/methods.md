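# Methods

## The system being modelled

`fedseg` reproduces, at desk scale, the architecture of
Personal-Health-Train-style federated deep-learning deployments for
tumour segmentation: hospitals ("data stations") hold preprocessed CT
slices and tumour masks behind their firewalls; a central coordinating
server registers entities, distributes tasks by a pull mechanism, and
stores only the final global model; a dedicated secure aggregation
server (SAS) — a station that holds no data — consolidates locally
trained models so that intermediate weights are isolated from the
coordinator, the researcher, and outsiders alike. In production systems
of this kind, the SAS front door is an API forwarder (conventionally on
port 5050) proxying to the aggregation algorithm's own API (port 7000),
both behind HTTPS; at desk scale this package binds the identical
request contract to an instrumented in-memory track instead (see
*Transport*), and no HTTP listener is built.

## Federated averaging and the synchronous barrier

Training is synchronous FedAvg. With K stations, station k holding
`n_k` local training cases and returning weights `w_t^k` at iteration
`t`, the server computes the parameter-wise convex combination

    w_{t+1} = Σ_k (n_k / Σ_j n_j) · w_t^k          (sample_weighted)

or the unweighted mean (`uniform`). Weighting is configurable with
`sample_weighted` as default, which is the standard FedAvg estimator
when sites differ in size. Accumulation runs in float64 and is cast back
to float32, so averaging one model — or two bit-identical models — is an
exact pass-through; the general case agrees with a scalar-by-scalar
reference loop to ≤1e-6.

The barrier is strict: aggregation fires exactly once per iteration, at
the moment the last expected station's submission is accepted, and never
before. Duplicate submissions within an iteration are refused
(first-wins), partial submissions are discarded if the iteration aborts,
and the *latest successful model* is never rolled back.

Weights, not gradients, are exchanged: each submission is a complete
parameter set, which avoids the classic gradient-leakage channel and
makes the latest-successful-model recovery semantics trivial.

## Token security

Every station↔SAS exchange requires a bearer token: a compact JWT
(HS256, per-task symmetric key created at task start) whose claims bind
it to one `(station, task, iteration, attempt)` with a validity window.
Defaults: lifetime 600 s, ±30 s clock-skew allowance, 0-based iteration
indexing. Validation is pure — it returns claims or raises a typed
rejection (forgery / replay / unknown-station / expiry) — so a refused
request provably leaves no state behind. Base64url segments must be
canonical; tokens that re-encode the same bytes differently are rejected
too.

The `attempt` claim exists for dropout recovery: when a failed iteration
is re-opened, the attempt counter bumps, so every token minted before
the abort is rejected as a replay even though the iteration index is
unchanged — this is what "fresh tokens per re-opened iteration" means
operationally.

Who mints tokens is a design choice here: the SAS mints them when an
iteration opens, and stations fetch theirs from the SAS's
`request-token` route, which checks roster membership only.
Authenticating the fetch itself is delegated to the transport layer
(mutually authenticated HTTPS in a real deployment, a trusted
in-process bus here), in the same way payload encryption is.

## Dropout recovery

On a reported station failure the current iteration aborts: partial
submissions are discarded, the iteration is re-opened with fresh tokens
(attempt+1) when the station returns, and training resumes from the
stored latest successful model. The recovery contract is: the pre-abort
aggregate is bit-unchanged, every station restarts the re-opened
iteration from it, and the next aggregation carries the original
iteration index — not zero. Straggler timeouts are a deployment policy
(hours in production, none in tests); the abort entry point is explicit
(`report_station_failure`) so tests can inject failures precisely.

## Coordinator

The coordinator relays metadata and control messages only; weight
traffic flows station↔SAS exclusively. Its persistence holds, per task,
exactly zero weight payloads until finalization and exactly one (the
final global model, as a digest-protected container) afterwards — an
auditable invariant, not a convention. Passwords are stored as salted
PBKDF2-HMAC-SHA256 digests and compared in constant time; unknown-user
and wrong-password failures are indistinguishable. Role permissions are
an explicit allow-list (researcher: submit/fetch-final/status; station
and aggregator: pull/report; aggregator only: store-final). Status cells
follow `pending → running → {completed, aborted}`, with `→ pending`
re-opening allowed only as part of dropout recovery. Persistence is an
in-memory store with an optional append-only JSONL journal; at the scale
this package targets (single process, few tasks) a journaled dict is the
whole database, and the audit surface (`audit_stored_weight_payloads`)
is what matters.

## Transport

All exchanges travel as frames: an 8-byte length, a JSON control
segment, and optionally one binary attachment that must be a valid
`.fweights` weight container. The in-memory track records every frame
verbatim, which makes the data-locality contract checkable rather than
aspirational: the audit decodes every frame, requires attachments to
parse as task-manifest weight containers, and searches all recorded
bytes for the raw float32/uint8 buffers of every phantom in the cohort.
A deployment would bind the same routes (`request-token`,
`get-global-model`, `submit-model`, coordinator register/authenticate/
task/status/final-model) over HTTPS; the in-memory track is the
reference implementation of that contract.

## The segmentation model

A 2D U-Net: `depth` encoder blocks (two 3×3 conv + ReLU, 2×2 max-pool),
a bottleneck, and mirrored decoder blocks (nearest-neighbour ×2
upsample, 3×3 up-convolution, skip concatenation, two 3×3 conv + ReLU),
with a 1×1 sigmoid head. Defaults: depth 2, 8 base filters, 64×64
inputs — 32,521 parameters, chosen so CPU training in seconds-to-minutes
is realistic while keeping the topology family of full-scale
segmentation networks. He-normal initialisation, zero biases,
deterministic in the seed.

Forward and backward passes are written directly in NumPy (im2col +
matmul convolutions, argmax-routed pooling); correctness is pinned by
float64 finite-difference gradient checks. This makes deterministic mode
exact: single-threaded CPU runs are bit-reproducible, and the test suite
asserts `federated == centralized` at zero tolerance rather than "close".

**Loss.** Default is `bce_dice`: pixel-wise binary cross-entropy plus
soft Dice (smoothing 1.0). Pure soft-Dice — the natural companion of the
Dice metric — turned out to have a hard failure mode at this scale: an
early over-large Adam step can collapse the prediction to all-background,
where the soft-Dice gradient is effectively dead and training never
recovers (observed on a measurable fraction of seed pairs). The BCE term
keeps per-pixel gradients alive through such collapses; `dice_loss`
remains available for experiments. Optimiser: Adam (lr 3e-3, β=0.9/0.999),
state created fresh inside each local training call — federated rounds
do not carry optimiser state, matching the weights-only exchange.

**Steps.** A "step" is one minibatch gradient update (batch 4 by
default). Production-scale deployments of such systems run on the order
of 10,000 steps per iteration on GPUs; the package defaults and tests
use tens-to-hundreds of steps on small phantom cohorts, which suffices
for every property under test and keeps full federations in CPU-minutes.

**Metrics.** Dice is `2|A∩B| / (|A|+|B|)` on thresholded (default 0.5)
predictions; both-empty masks score 1.0 (correct-rejection convention,
stated because conventions differ). `val_dice_global` at iteration `i`
always scores the *incoming* model — the aggregate of iteration `i−1` —
before local training; `val_dice_local` additionally scores the freshly
trained local model. The off-by-one is deliberate and tested: it mirrors
evaluating "the intermediate averaged model on the validation sample" at
the start of each cycle.

## Weight container

`.fweights` is the exchange and storage format: an 8-byte magic, a JSON
manifest (dtype tag, byte order, per-entry name/shape/offset/length,
provenance metadata, payload SHA-256), then the concatenated
little-endian float32 payload. The digest is verified before any array
is materialised, so truncation or bit-flips cannot yield a partial
weight set. Round trips are bit-exact and fuzz-tested.

## The phantom generator

Each site profile describes one synthetic hospital: patient count,
additive grey-level offset (scanner calibration differences), Gaussian
noise level, tumour radius range, lung-ellipse geometry, and a seed.
A case is a 64×64 float32 image — background 20, elliptical "lung"
region at 110 + site offset, one quasi-elliptical tumour blob at +90
contrast — plus the binary tumour mask. Tumour ellipses get ±10% axis
jitter, random rotation, and smooth low-harmonic boundary perturbation
(the jitter is capped at 10% so that a fixed-radius-r tumour's pixel
count always stays within the rasterised discs of radius r−0.5 and
r+0.5, which is the generator's own testable contract). Masks are
clipped to the lung region, so containment is an invariant rather than a
probability.

Determinism: case `i` of a profile is a pure function of
`(profile.seed, i)` via independent per-case RNG streams, so growing a
site never changes existing patients and full-cohort regeneration is
bit-identical. Patient identifiers embed the site id, making cross-site
overlap impossible by construction — the horizontal-partitioning
invariant. Splits are per-site deterministic shuffles with
`n_val = max(1, round((1−f)·n))`; a single-patient site is a
configuration error because every station must keep a local validation
sample.

What the phantoms do *not* emulate: 3D anatomy, DICOM/HU calibration,
registration artefacts, multiple or absent tumours, inter-observer
delineation variability, and realistic class imbalance at clinical
resolution. Passing tests therefore demonstrate the correctness of the
*federation machinery* and the learnability of a clean segmentation
signal — not clinical-grade segmentation accuracy.

## Numerical and degenerate-input choices

- FedAvg accumulates in float64, emits float32; `sample_weighted`
  requires every contributor's `n_k > 0`, otherwise it is an error.
- `steps=0` local training returns its input bit-identically with the
  loss reported as missing.
- Dice on non-binary or shape-mismatched masks is an error, never a
  coercion.
- Prediction threshold must lie strictly in (0,1); default 0.5.
- Iterations are 0-based everywhere, including token claims and weight
  metadata; the model released at iteration `i ≥ 1` carries
  `meta.iteration = i−1`, and the initial model carries 0 with no
  contributing stations, which is how it is told apart from the
  iteration-0 aggregate.
- History wall-clock columns are excluded from reproducibility
  comparisons; everything else in two deterministic runs is identical.

## Problem sizes used in the checks

The automated checks run: FedAvg fuzzing over ~100 random manifests;
a K=1 federation of 3 iterations × 50 steps on 20 phantoms against a
plain-loop reference (zero tolerance); a K=2 identical-stations
collapse; barrier orderings for K ∈ {2,3,5}; ~130 forged/mutated/stale
tokens against ~120 honest ones; a K=3 dropout-recovery run of 4
iterations; live storage and data-locality audits over full runs; and a
K=3 heterogeneous learning run (40 train / 10 validation per site, 10
iterations × 100 steps) that reaches mean validation Dice ≥ 0.6 — in
practice ≈ 0.99 — from ≈ 0 at initialisation. These sizes are the
package's chosen desk-scale study conditions: small enough for a single
CPU core in minutes, large enough that every contract is exercised
end-to-end.

## Known limitations

- No network binding is included; multi-host deployment would add an
  HTTPS binding of the documented routes plus real key distribution.
- The SAS trusts the transport to authenticate token-fetch requests;
  a hostile transport could obtain a token for a rostered station.
- Synchronous training means the slowest station gates every iteration;
  no asynchronous or partial-participation scheme is implemented.
- Single task at a time per SAS state; no scheduling fairness.
- The NumPy U-Net is CPU-only and unsuitable for clinical-resolution
  images; it is the point of the exercise, not a production model.
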