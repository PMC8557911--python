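import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sewagesense import ASVTable, SourceDatabase, SourceRecord

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def make_table(counts_by_sample, sequences):
    """counts_by_sample: {sample: {asv: count}}; sequences: {asv: seq}."""
    counts = pd.DataFrame(counts_by_sample).T.fillna(0).astype(int)
    counts = counts[list(sequences)]
    return ASVTable(counts=counts, sequences=dict(sequences))


@pytest.fixture(scope="session")
def toy_table():
    """Two samples, four ASVs with known proportions (70/25/5/0 in s1)."""
    seqs = {"a_fw": "ACGT" * 10, "a_sw": "TGCA" * 10,
            "a_hf": "GGCC" * 10, "a_un": "ATAT" * 10}
    counts = {"s1": {"a_fw": 70, "a_sw": 25, "a_hf": 5, "a_un": 0},
              "s2": {"a_fw": 50, "a_sw": 0, "a_hf": 0, "a_un": 50}}
    return make_table(counts, seqs)


@pytest.fixture(scope="session")
def toy_databases(toy_table):
    fw = SourceDatabase([SourceRecord("fw_0", toy_table.sequences["a_fw"], "freshwater")],
                        source="freshwater")
    sw = SourceDatabase([SourceRecord("sw_0", toy_table.sequences["a_sw"], "sewer", 0.5)],
                        source="sewer")
    st = SourceDatabase([SourceRecord("st_0", toy_table.sequences["a_hf"], "human_stool", 0.5)],
                        source="human_stool")
    return fw, sw, st


def brute_force_percentile(values, q):
    """Independent order-statistic interpolation (inclusive linear method)."""
    v = sorted(values)
    if len(v) == 1:
        return v[0]
    h = (len(v) - 1) * q / 100.0
    lo = int(np.floor(h))
    frac = h - lo
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + frac * (v[hi] - v[lo])


def brute_force_partition(table, fw_db, sw_db, st_db, q=5.0):
    """Exhaustive reimplementation of the partitioning rules.

    All-pairs string comparison for matching; manual percentile; freshwater
    precedence then stool then sewer; strict 5th-vs-95th inclusion filter.
    """
    totals = {s: sum(table.counts.loc[s]) for s in table.sample_ids}
    out = {}
    for asv in table.asv_ids:
        seq = table.sequences[asv]
        category, ref = "uncategorized", None
        fw_hit = [r.reference_id for r in fw_db if r.sequence == seq]
        if fw_hit:
            out[asv] = ("freshwater", fw_hit[0])
            continue
        for db, cat in ((st_db, "human_fecal"), (sw_db, "sewer")):
            hits = [r for r in db if r.sequence == seq]
            if not hits:
                continue
            rel = [table.counts.loc[s, asv] / totals[s]
                   for s in table.sample_ids if totals[s] > 0]
            p5 = brute_force_percentile(rel, q)
            if p5 < hits[0].sewage_p95:
                category, ref = cat, hits[0].reference_id
            break
        out[asv] = (category, ref)
    return out


def random_partition_instance(rng, n_asvs=None, n_samples=None, seq_len=12):
    """A random table + databases with deliberate cross-database overlaps."""
    n_asvs = n_asvs or rng.integers(5, 51)
    n_samples = n_samples or rng.integers(1, 11)
    pool = list({random_dna(rng, seq_len) for _ in range(3 * n_asvs)})
    rng.shuffle(pool)

    def db(source, n, offset):
        recs = []
        for i in range(n):
            seq = pool[(offset + i) % len(pool)]
            p95 = None if source == "freshwater" else float(rng.uniform(1e-6, 1.0))
            recs.append(SourceRecord(f"{source}_{i}", seq, source, p95))
        # de-duplicate within the database
        seen, kept = set(), []
        for r in recs:
            if r.sequence not in seen:
                seen.add(r.sequence)
                kept.append(r)
        return SourceDatabase(kept, source=source)

    fw = db("freshwater", int(rng.integers(1, 12)), 0)
    sw = db("sewer", int(rng.integers(1, 12)), int(rng.integers(0, 8)))
    st = db("human_stool", int(rng.integers(1, 12)), int(rng.integers(0, 16)))

    all_ref_seqs = [r.sequence for d in (fw, sw, st) for r in d]
    seqs, seen = {}, set()
    i = 0
    while len(seqs) < n_asvs:
        if rng.random() < 0.6 and all_ref_seqs:
            cand = all_ref_seqs[rng.integers(0, len(all_ref_seqs))]
        else:
            cand = random_dna(rng, seq_len)
        if cand not in seen:
            seen.add(cand)
            seqs[f"asv_{i}"] = cand
            i += 1
    counts = pd.DataFrame(
        rng.integers(0, 200, size=(n_samples, n_asvs)),
        index=[f"s{j}" for j in range(n_samples)], columns=list(seqs))
    # guarantee at least one sample with nonzero total
    if (counts.sum(axis=1) == 0).all():
        counts.iloc[0, 0] = 1
    return ASVTable(counts=counts, sequences=seqs), fw, sw, st
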