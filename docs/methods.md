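# Methods

## Model and assumptions

The protocol deduplicates a horizontally partitioned virtual dataset held
by N ≥ 3 data custodians, assisted by a semi-trusted coordinator. All
parties are semi-honest: they follow the protocol but may try to infer
private information from the messages they see. Channels between parties
are assumed secure; the coordinator participates without input, holds
neither secret key, and is assumed not to collude with a custodian. Under
these assumptions the intended information flow is:

- a custodian learns which of **its own** IDs occur more than once in
  the virtual dataset — nothing about IDs it does not hold, and nothing
  about other custodians' record counts;
- the coordinator sees only uniformly masked counting Bloom filters and
  keyed hashes of candidate IDs;
- the known limits are inherent to the design and documented rather than
  patched: the two ring neighbours of a custodian can jointly reconstruct
  its random mask (and hence, with the coordinator's help, its input) —
  the stated collusion bound — and the coordinator necessarily observes
  *which custodians* share a candidate hash in the resolution stage,
  though not what the hash means.

## Counting-filter algebra

All counters live in Z_{2^c}. Modular arithmetic is a deliberate choice:
it makes `sub` the exact inverse of `add`, and it makes masking
information-theoretically hiding — for any fixed filter x and an
independent uniform mask r, `add(x, r)` is itself uniform, exactly as a
one-time pad. The random mask generator draws each counter i.i.d.
uniform on [0, 2^c − 1] from a seeded PCG64 stream; uniformity over the
full ring is the unique distribution with this property, which the test
suite checks by chi-square (α = 0.01) on pooled masked counters.

The default counter width is c = 32, so true aggregate counts never wrap
at realistic scales; `setup` refuses a session where n·N ≥ 2^c. Tests of
the algebra use c = 8 for cheap chi-square power; the laws hold for any
c ≥ 2.

The k position functions are derived from one keyed BLAKE2b hash by
prefixing the function index to the element bytes and reducing mod m
(0-based positions). Elements are hashed as UTF-8 of the trimmed,
case-preserved identifier string, so independent parties holding the key
agree bit-exactly. Position derivation increments one counter per hash
function; if two functions collide on a position for the same element,
that counter advances by 2 — the standard counting-filter convention.

## Parameter sizing

`size_parameters(n, p_target)` returns the smallest array meeting the
false-positive target: for each candidate k, the minimal m with
(1 − e^(−kn/m))^k ≤ p is m_k = ⌈kn / −ln(1 − p^(1/k))⌉, and the best k
is taken. This tracks the classical optimum m = −n·ln p/(ln 2)²,
k = (m/n)·ln 2, while making the guarantee exact rather than
approximate. Default p_target is 10⁻⁴; the expected element count n is a
jointly agreed public parameter — the orchestrator defaults it to the
total extract size, which in a deployment would be replaced by an agreed
upper bound so that no exact count is shared.

## Duplicate identification and the false-positive bound

Each custodian's candidate list L_i contains its IDs whose estimated
global multiplicity (minimum counter over the ID's k positions in
CBF_S ∩ BF_I^i) is ≥ 2. True duplicates are always found: an ID present
at d custodians contributes exactly d to each of its positions, and the
minimum-counter estimate never underestimates. A singleton enters L_i
only if other elements cover all k of its positions — the ordinary Bloom
false-positive event, rate ≈ (1 − e^(−kn/m))^k at the sized parameters
(plus a vanishing self-collision term when an element's own positions
repeat). The resolution stage removes every such false positive, since
its keyed hash appears in only one custodian's sorted list; final output
is therefore invariant to p_target, which only trades candidate-list
size against filter size.

One numerical footnote: a masked filter position whose counter is
exactly 0 (probability 2^−c per position) would drop out of the
footprint mask BF_{r∪I}^i and could in principle suppress a true
candidate. At the default c = 32 this is a ~10⁻⁹-per-position event and
is accepted; protocol-level tests run at c = 32.

## Message accounting

The audit counts, per party, messages sent and received, and checks the
closed forms: non-leader custodians 3 sent / 3 received, leader N + 2
sent, coordinator 2N/2N, total 6N − 1. The accounting convention is that
the leader's broadcast of the mask total CBF_R — implemented as N − 1
point-to-point messages and tagged as broadcast payloads — is counted on
the send side but reported separately from per-party receive tallies;
that is the only convention under which all the closed forms hold
simultaneously, and the audit reports broadcast deliveries in their own
column so nothing is hidden. The audit also asserts the structural
privacy contract: every coordinator-bound payload is a well-formed
masked filter of the session's parameters or a keyed hash list, and no
payload contains secret-key material or a plaintext identifier (filter
payloads, being base64-packed masked counters, are checked structurally;
hash-list payload tokens are matched exactly against the identifier
universe).

## Sorted-neighborhood resolution

Confirmed duplicates are exact equalities of keyed hashes, so the merged
sorted list is scanned for maximal runs of equal hashes — equivalent to
any sliding window of size ≥ 2 for exact matching. The window size
remains a config knob (default 2) for forward compatibility with
approximate sorting keys, where window semantics would genuinely matter;
no approximate semantics are guessed here. The keeper of each confirmed
group is the lowest-ring-index custodian holding it — any single-keeper
rule satisfies the requirement; this one is deterministic and auditable.

## Deterministic linkage extension

A match criterion is an ordered list of quasi-identifier fields with a
per-field normalization recipe (trim, case-fold, collapse whitespace;
dates canonicalized to ISO; unique IDs trimmed only). Records missing a
criterion field are excluded from that criterion's instance rather than
matched on empty strings, which would fabricate duplicates. One protocol
instance runs per criterion with fresh secret keys (derived from
(master seed, instance index)); a record pair is a duplicate iff matched
under at least one criterion, and matched pairs are merged transitively
so a single keeper per combined group is well defined.

The base unique-ID protocol is the p = 1 instance of the same engine, so
the single-criterion run on the unique ID reproduces the base report bit
for bit by construction. For p > 1, each instance's resolution message
carries its confirmed matches (paired with keyed record handles, hashed
under a handle key shared by custodians across instances and unknown to
the coordinator), and one extra round of N removal messages applies the
keeper decision on the merged groups — total traffic p(6N − 1) + N,
linear in p; each per-instance transcript still audits to 6N − 1.

## Synthetic data generator

The generator emulates distributed microbiology surveillance extracts:
records carry an 11-digit synthetic personal number (no valid check
digits — deliberately not a real-format identifier), name, sex, date of
birth, postal-style area code, infectious agent, test result and test
date (defaults span January 2015 – April 2016). Records are split
equally across custodians (±1). Duplicates are planted by overwriting
exactly ⌊rate · n_i⌋ records per custodian with copies of *original*
records held at other custodians, so every group spans ≥ 2 custodians;
the default group size is 2, with a configurable fraction of copies
extending groups to a third custodian. Copies optionally carry
case/whitespace noise on name fields — noise that linkage-key
normalization must undo, which the tests exploit. A rate is rejected as
infeasible when some custodian would need more distinct originals than
the other custodians can host (under equal allocation this caps the rate
at (N − 1)/N).

What the generator does **not** emulate: realistic name/area frequency
distributions (fields are drawn uniformly from small pools),
typographical errors beyond case/whitespace, within-custodian repeat
records, missing-data patterns, or temporally clustered disease
episodes. Passing tests therefore demonstrate protocol correctness —
exact agreement with plaintext deduplication on the generated inputs —
not linkage quality on messy real-world quasi-identifiers, where
deterministic criteria inherently trade recall for precision.

The plaintext oracle deduplicates in the clear (exact unique-ID
equality, or any-criterion key equality transitively closed, same keeper
rule) and is the reference for every end-to-end equivalence test.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the full protocol on
grids of N ∈ {3, 5, 10} custodians, 1 000–20 000 records and duplicate
rates 0–10%, with the runtime-scaling check fitting total runtime over
2 000–20 000 records (R² of a linear fit ≥ 0.95; each point is the best
of three process-CPU-time measurements, which damps scheduler and
garbage-collection noise without changing the quantity measured). These
sizes exercise
every code path at full fidelity — the protocol's cost is linear in the
record count, so behaviour at these scales is representative, and all
correctness properties checked are exact rather than asymptotic.

## Known limitations

- Single-process simulation: transports are in-process channels; no
  network deployment, authentication, or malicious-adversary hardening.
- The security argument is structural (transcript contents and payload
  types), not a mechanized proof.
- Within-custodian duplicates are out of scope by design: each custodian
  contributes a *set* of IDs, and local repeats are the custodian's own
  preprocessing concern.
- Probabilistic (Fellegi–Sunter) linkage and approximate string matching
  are out of scope; criteria are strictly deterministic.
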