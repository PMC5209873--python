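# ppdedup

Privacy-preserving deduplication of horizontally partitioned health data.

## The problem

Distributed disease-surveillance networks pool statistics over a *virtual
dataset*: each data custodian (e.g. a microbiology laboratory) runs the
same query locally and only aggregates leave the institution. When a
patient is tested at several laboratories — transferred samples, changed
providers, repeat testing — the same person appears in more than one
partition and a simple sum of local counts overestimates. Deduplicating
across custodians, however, must not reveal patients' identifiers held by
other institutions, and must not reveal any custodian's record count,
which institutions treat as competitively sensitive.

`ppdedup` implements a secure deduplication protocol for N ≥ 3 custodians
and a semi-trusted coordinator (who participates without input and holds
no secret keys), under the semi-honest adversary model. After a run, each
custodian knows which of *its own* records were duplicated elsewhere, the
duplicates are deleted with exactly one keeper per group, and nothing
else leaks. The package simulates all parties in one process with a full
message transcript, so every privacy and complexity claim is auditable.

## The method

The unit of exchange is the **counting Bloom filter** (CBF): an array of
m counters mod 2^c into which elements are inserted at k positions
b_h(x) = H_h(x) mod m derived from a keyed hash (key k₁). The multiset
algebra — `add`, `sub`, `intersect`, `count`, `toBloomFilter` — is exact
modular arithmetic, so a CBF masked by i.i.d.-uniform random counters is
information-theoretically hiding, and subtraction inverts addition
exactly.

1. **Secure sum** — the custodians pass their random masks CBF_r^i around
   a ring; the leader adds and later strips an initial mask CBF_r^0 and
   broadcasts the mask total CBF_R.
2. **Secure duplicate identifier** — each custodian sends
   add(CBF_r^i, CBF_I^i) to the coordinator, who aggregates CBF_{R∪S} and
   returns each custodian its masked slice. Locally subtracting CBF_R's
   matching slice exposes CBF_S ∩ BF_I^i, from which the custodian reads
   the global multiplicity of each of its IDs. IDs with multiplicity ≥ 2
   form the candidate list L_i: every true duplicate (no false
   negatives) plus Bloom false positives at rate ≈ (1 − e^(−kn/m))^k,
   sized to a target probability.
3. **Distributed sorted neighborhood** — candidates are hashed with a
   second key k₀, locally sorted, merged at the coordinator; runs of
   equal hashes spanning ≥ 2 custodians are confirmed duplicates. The
   lowest-ring-index holder keeps the record; the rest delete. Bloom
   false positives (single-custodian hashes) are discarded here.

Message complexity is closed-form: each non-leader custodian sends 3 and
receives 3 messages, the leader sends N + 2, the coordinator sends and
receives 2N — 6N − 1 messages in total, linear in N.

When no reliable unique ID exists, deterministic **linkage keys**
(normalized concatenations of quasi-identifiers, e.g. name + sex + date
of birth) replace it: one protocol instance per match criterion, a pair
is a duplicate if any criterion matches, and groups are merged
transitively before the keeper rule is applied once.

## Worked example

```python
from ppdedup import (GeneratorSpec, generate_vd, plaintext_oracle,
                     ProtocolConfig, deduplicate)

spec = GeneratorSpec(n_custodians=5, total_records=1000,
                     duplicate_rate=0.05, seed=7)
vd, truth = generate_vd(spec)
report = deduplicate(vd, ProtocolConfig(p_target=1e-4), master_seed=7)

audit = report.instances[0]["audit"]
oracle = plaintext_oracle(vd)
print(f"records before: {vd.total_records}")
print(f"duplicate groups found: {len(report.groups)} "
      f"(planted: {len(truth.groups)})")
print(f"records removed: {sum(len(v) for v in report.removals.values())}")
print(f"records after: {report.vd_after.total_records}")
print(f"matches plaintext oracle: {report.removals == oracle.removals}")
print(f"messages: {audit['total_messages']} (6N-1 = {6*5-1}), "
      f"audit passed: {audit['passed']}")
```

prints

```
records before: 1000
duplicate groups found: 50 (planted: 50)
records removed: 50
records after: 950
matches plaintext oracle: True
messages: 29 (6N-1 = 29), audit passed: True
```

1000 records across 5 laboratories with 5% planted cross-custodian
duplicates yield 50 duplicate groups; the protocol finds all 50, removes
one copy per group (keeping the lowest-indexed custodian's record), and
agrees exactly with deduplication computed in the clear — while the
transcript shows the coordinator only ever received masked filters and
keyed hash lists, in exactly 6N − 1 = 29 messages.

The same workflows are available from the shell:

```
ppdedup generate -N 5 -t 1000 -r 0.05 -s 7 -o data/
ppdedup run -e data/extract_D01.tsv ... -e data/extract_D05.tsv -s 7 -o report.json
ppdedup verify -r report.json -g data/ground_truth.json
ppdedup audit -r report.json
```

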