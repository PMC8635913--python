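# Methods

This note documents the models, numerical choices, and design decisions
behind the simulator, and what its tests do and do not establish.

## Scope and simulation model

The package simulates, in a single process, a federation of K clinical
devices coordinated by a blockchain maintained by a set of miner nodes.
Networking is abstracted to synchronous broadcast: every miner sees every
transaction, every device sees the latest block. Forking, asynchrony,
partitions, and proof-of-work/stake are out of scope. Signatures are a
deterministic HMAC-SHA256 simulation behind a pluggable `SignatureScheme`
interface: each party holds a registered secret, signing is
HMAC(secret, message), and the key registry plays the role of a PKI.
This gives the protocol the properties it actually relies on in simulation
(per-party deterministic signatures over canonical bytes, verifiable by the
committee and the auditor); forgery and key exchange are not modeled.

## Synthetic clinical data

`generate_pima_like` draws eight non-negative integer features from
truncated Gaussians correlated through a single latent "metabolic risk"
factor, with per-column means and ranges plausible for a diabetes cohort
(fixture constants, not estimates of any real cohort). The
DiabetesPedigreeFunction column is stored ×100 so an integer column keeps
two significant digits. Labels follow Bernoulli(sigmoid(z·β* + b)) on the
standardized features with a fixed ground-truth coefficient vector β*
(risk increasing in every predictor, dominated by glucose, BMI, and age);
the intercept b is set by bisection so the realized mean probability equals
the requested positive rate (default 0.35). β* and b are recorded in the
dataset's provenance, which is what makes parameter-recovery and
separability tests possible.

What the generator does **not** emulate: the real Pima cohort's marginal
distributions and missing-data conventions (zeros encoding missingness),
label noise beyond the logistic link, and non-IID device heterogeneity —
shards are an even random partition (sizes differing by at most one).
Passing tests therefore demonstrate correctness of the mechanisms on a
well-specified, learnable task, not clinical performance on real data.

Default experiment sizes: n = 768 samples split 70:30 and partitioned over
K = 20 devices (shards of 26–27 samples); the recovery and robustness
property tests use n = 5000 (shards of 175), where shard gradients are
informative enough for clean geometric separation.

## Local models and training

All backends expose parameters as one flat float64 vector (per layer:
weights row-major, then biases), initialized with weights ~ N(0, 0.02²)
and zero biases. The tested training path is tabular: binary logistic
regression (9 parameters) by default, optionally a one-hidden-layer tanh
MLP (178 parameters). A 28×28 LeNet-style CNN (two 5×5 convolutions with
32/64 filters, 2×2 poolings, dense 512, dense 10; 1,663,370 parameters) is
provided for the parameter-count contract and initialization only — there
is no meaningful way to feed 8 tabular features to it, so it takes no part
in the pipeline.

A device's per-round "gradient" is the accumulated parameter delta
w_in − w_out over `local_iterations` mini-batch SGD steps (batches sampled
without replacement, reshuffled per epoch; a batch size exceeding the shard
silently becomes full-batch, which the default 64-vs-27 configuration
triggers). The server step is 1: the global update subtracts the plain mean
of the block's qualified gradients. Features are standardized once, with
the generator's fixed column constants rather than data-dependent
statistics, so the transform is identical across shards and leaks nothing.
The default learning rate is 0.1, chosen so that 30 clean federated rounds
on n = 5000 match a centrally fit logistic model within a fraction of a
percentage point of accuracy (asserted in the suite).

## Adaptive differential privacy

The clipper state holds the scalar prior E[g̃²], interpreted as an EMA of
the **squared L2 norm** of the released global gradient — the only
dimensionally consistent reading, since √E[g̃²] is used directly as a
scalar L2 threshold. Defaults: γ = 0.1, β = 1.2, C = 3, G = 1e-6, σ = 4.
At the boundary E[g̃²] = G exactly (which the two strict inequalities of
the threshold rule leave open) the fixed-C branch is used: conservative
early-stage behavior. G is a configuration constant; a helper can instead
set it to the prior observed in a chosen round. Noise is i.i.d. Gaussian
with per-coordinate standard deviation C_t·σ added after clipping; each
(device, round) pair has its own named noise stream.

**σ = 0 disables the whole mechanism** — no clipping, no noise, no prior
tracking — not merely the noise term. Clipping without noise provides no
privacy, and only under this semantics does the no-privacy pipeline reduce
*bit-identically* to plain federated averaging (an equivalence the suite
asserts over ten rounds). It also matters for the robustness benchmarks: an
adaptively shrinking threshold normalizes all updates onto a small sphere
and erases the norm separation that distance-based verification exploits.

### Behavior at the default noise scale

At the reference settings the mechanism adds per-coordinate noise of
standard deviation C_t·σ = 12 to an update whose entire L2 norm is at most
C_t = 3. Even for the 9-parameter logistic backend the released vectors are
then noise-dominated, with two consequences the test suite measures rather
than hides. First, multi-KRUM distances are dominated by noise, so
detection of label-flipped devices is near chance (the σ = 0 benchmarks,
where detection is essentially perfect, isolate the verification logic from
this effect). Second, the prior EMA feeds back on itself: the released
global gradient's squared norm is ≈ d(C_tσ)²/m for d parameters and m
aggregated updates, which at the defaults multiplies the prior by ≈ 2.4 per
round, so C_t grows without bound instead of tracking convergence — and the
late-training attack success rate recomputed by `scripts/acceptance.py`
sits near 50%, the level of a noise-driven model. The equations are
implemented exactly as stated; the alternative convention in which noise is
measured against the aggregate (per-coordinate std σ·C/L for lot size L)
would change both behaviors, and can be explored through the accountant's
`normalized` mode and a small σ, but is deliberately not substituted into
the release path.

## Moments accountant

Per round and device the accountant adds the log-moment
α(λ) = log max(E1, E2) of the pair μ₀ = N(0, s²), μ₁ = N(1, s²) and
mixture μ = (1−q)μ₀ + qμ₁, on the integer grid λ = 1..100 (λ = 0 is
vacuous). The expectations are evaluated by adaptive vector quadrature on a
finite interval covering every component's support, **in log-space**: each
λ's log-integrand is shifted by its maximum (located on a 4001-point coarse
grid) before exponentiation, so moments far beyond float range compose
without overflow; absolute/relative quadrature tolerances are 1e-11, and a
failed integration raises rather than returning NaN. At q = 1 the
quadrature reproduces the closed form λ(λ+1)/(2s²) to better than 1e-6
relative (asserted); at q = 0, α ≡ 0. Tiny negative quadrature jitter is
clamped at zero, matching α ≥ 0.

The sampling probability is q = min(1, batch/shard); the default experiment
therefore runs at q = 1 (its batch of 64 exceeds the 27-sample shards). One
release per device per round is accounted — the local iterations produce a
single noised upload. Composition defaults to the strict sum over devices
and rounds (ε grows with K); `rounds_only` implements parallel composition
across devices holding disjoint data and is selectable. The mechanism
convention defaults to `absolute` (unit shift, s = C_t·σ), under which
a *growing* C_t makes later rounds cheaper and a shrinking one makes them
dearer; `normalized` (s = σ, noise in sensitivity units) makes α
independent of C_t. Both behaviors are asserted by tests so the divergence
is documented, not hidden.

ε(δ) = min over the λ grid of (α(λ) + log(1/δ))/λ; an empty ledger spends
ε = 0, spent ε is non-decreasing by construction, and training halts when
it exceeds the budget (default ε = 3, δ = 1e-4).

## Verification and consensus

Multi-KRUM uses plain (unsquared) Euclidean distances — each gradient's
score is the sum of distances to its R−f−2 nearest peers — with the
squared variant of the original literature behind a flag. f defaults to
⌈0.3·R⌉ (the assumed poisoned share) and is configurable; pools must
satisfy R ≥ f + 3. The R−f lowest scores qualify, ties broken by ascending
device id. Every committee member recomputes scores independently and signs
the gradients it finds qualified; acceptance requires a strict majority
(> M/2) of valid signatures, so a single colluding verifier cannot push a
rejected gradient through. Note that selection always rejects exactly f
submissions: once real attackers are blacklisted, the rejections
necessarily fall on honest devices, which is a property of the rule, not a
bug — reputations still drift upward on average because qualification is
the more frequent event.

Committee selection hashes deterministically: h₀ is the previous block's
hash, h_{k+1} = SHA-256(h_k), each digest taken mod the ring size selects
an arc owner, duplicates are skipped. Arcs are contiguous integer intervals
in ascending miner-id order with length equal to reputation, so
proportionality holds by construction (and is verified empirically by a
chi-square test over 10⁴ hashes). The leader is the committee member
indexed by SHA-256(prev_hash ‖ "leader") — deterministic where the
protocol only says "randomly chosen", trading nothing but unpredictability
we do not model for reproducibility. Block approval needs a strict > 2M/3
vote; a failed vote appends an *empty* block (correct prev_hash, no
transactions) so the chain never stalls, and the leader of a rejected block
loses a reputation point.

Reputation moves ±1: devices by qualification/rejection (only in rounds
that produced a non-empty block), verifiers by agreement with the final
accepted set, floor at zero with permanent blacklisting. Initial reputation
defaults to 10 for every party (the protocol leaves the value open).
Blacklisted devices' transactions are dropped before verification and
their shards are simply unused.

## Attack harness

The adversary is static: a seeded draw designates round(fraction·K)
devices before training and every label in their shards is inverted
(features byte-identical) — the strongest static label-flipping variant.
The per-round detection set is defined as every device whose update is
excluded from the block, whether rejected by multi-KRUM that round or
already blacklisted; a blacklisted attacker is a detection success, not a
miss. Malicious verifiers (sign the complement of the qualified set,
dissent on valid blocks) exercise the majority-signature and approval
defenses and are meant to stay below one third of the miners, matching the
protocol's honest-majority assumption.

## Numerical and engineering choices

* Canonical serialization: 8-byte big-endian integers, length-prefixed
  byte strings, documented field order; gradients as little-endian float64.
  Block hash = SHA-256 of the full canonical bytes; the leader signs the
  header digest. Chains persist as one binary file per block plus a JSON
  index, and `Chain.audit` re-verifies every link, signature, and
  endorsement majority.
* Clipping is idempotent to one ulp (rescaling by ‖g‖/C can leave the
  recomputed norm a rounding step above C); tests assert at that precision.
* A non-finite global gradient leaves the clipper prior unchanged with a
  warning (a diverged round should not poison the EMA).
* Convergence stop: relative training-loss change below 1e-4 for five
  consecutive rounds (configurable; a tolerance of 0 disables it for
  fixed-horizon runs).
* All sub-streams (data, split, partition, init, per-device-per-round
  batching and noise, attack designation) are named `SeedSequence` children
  of the experiment seed.

## Known limitations

* Single-process simulation; no real networking, no wall-clock fidelity.
* The HMAC signature simulation models integrity within the simulation,
  not public verifiability against outside adversaries. (Pluggable if a
  real scheme is wanted.)
* At the default σ = 4 the printed noise scale overwhelms the updates of
  small tabular models, as analysed above; utility-bearing DP runs at these
  equations require either much smaller σ or the normalized convention.
* The CNN backend is a parameter-count and initialization contract only.
* The external-CSV loader is provided but the package makes no claims about
  behavior on the real Pima data.
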