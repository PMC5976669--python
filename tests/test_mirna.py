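"""Seed scanner, consensus rule, score filters, sponges and pre-miRNA search."""

import numpy as np
import pandas as pd
import pytest

from degradome.io import ValidationError
from degradome.mirna import (
    TargetSite,
    apply_score_filters,
    consensus_targets,
    find_harbored_premirnas,
    find_sponge_candidates,
    reciprocal_expression_filter,
    revcomp,
    scan_seed_sites,
    scan_transcriptome,
    seed_site_string,
)
from degradome.simulate import transcript_utr3s

MIR = "TGGAATGTAAAGAAGTATGTAT"  # 22 nt


def _embed(site, rng, length=300):
    bg = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    pos = length // 2
    return bg[:pos] + site + bg[pos + len(site):], pos


def test_planted_8mer_found_with_class_and_coords(rng):
    site = seed_site_string(MIR, "8mer")
    seq, pos = _embed(site, rng)
    hits = [s for s in scan_seed_sites(MIR, seq) if (s.start, s.end) == (pos, pos + 8)]
    assert hits and hits[0].site_class == "8mer"


@pytest.mark.parametrize("cls,length", [("8mer", 8), ("7mer-m8", 7), ("7mer-A1", 7), ("6mer", 6)])
def test_site_string_lengths_match_class(cls, length):
    assert len(seed_site_string(MIR, cls)) == length


def test_scanner_is_deterministic_and_respects_utr(rng):
    site = seed_site_string(MIR, "8mer")
    seq, pos = _embed(site, rng, length=600)
    a = scan_seed_sites(MIR, seq)
    b = scan_seed_sites(MIR, seq)
    assert a == b
    inside = scan_seed_sites(MIR, seq, region="utr3", utr3=(pos - 10, pos + 20))
    assert any(s.start == pos for s in inside)
    outside = scan_seed_sites(MIR, seq, region="utr3", utr3=(0, 50))
    assert all(s.start != pos for s in outside)
    with pytest.raises(ValidationError):
        scan_seed_sites(MIR, seq, region="utr3", utr3=None)


def test_6mer_background_rate_matches_combinatorial_null(rng):
    """E[count] for a fixed 6mer in random sequence is (L-5)/4^6."""
    core = seed_site_string(MIR, "6mer")
    L, reps = 1000, 1000
    counts = []
    for _ in range(reps):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=L))
        counts.append(sum(1 for s in scan_seed_sites(MIR, seq)))
    mean = np.mean(counts)
    expected = (L - 5) / 4**6
    se = np.std(counts, ddof=1) / np.sqrt(reps)
    assert abs(mean - expected) < 3 * se + 1e-9
    assert core == revcomp(MIR[1:7])


def test_planted_sites_recovered_with_recall_one(genome):
    records, seqs, truth = genome
    utr3s = transcript_utr3s(seqs, truth.transcripts)
    sites = scan_transcriptome(truth.mirna_seqs, seqs, truth.transcripts, utr3s, min_class="8mer")
    found = {(s.mirna, s.transcript, s.start, s.end) for s in sites}
    planted = set(map(tuple, truth.seed_sites))
    assert planted <= found
    assert found == planted  # chance copies were scrubbed by the generator


# ---------------------------------------------------------------------------
# Consensus


def _site(src, start, end, mir="m1", tx="t1"):
    return TargetSite(mir, tx, "full", start, end, "6mer", sources=frozenset({src}))


def test_identical_sites_from_three_sources_merge():
    sets = {s: [_site(s, 10, 16)] for s in ("miranda", "pita", "targetspy")}
    (cons,) = consensus_targets(sets)
    assert (cons.start, cons.end) == (10, 16)
    assert cons.sources == {"miranda", "pita", "targetspy"}


def test_quorum_not_met_is_empty():
    sets = {"miranda": [_site("miranda", 10, 16)], "pita": [_site("pita", 12, 18)], "targetspy": []}
    assert consensus_targets(sets, k_required=3) == []


def test_staggered_overlap_intersection_and_exact_switch():
    sets = {
        "a": [_site("a", 10, 18)],
        "b": [_site("b", 14, 22)],
        "c": [_site("c", 16, 24)],
    }
    (cons,) = consensus_targets(sets)
    assert (cons.start, cons.end) == (16, 18)  # brute-force interval intersection
    assert consensus_targets(sets, exact=True) == []
    disjoint = {"a": [_site("a", 0, 6)], "b": [_site("b", 20, 26)]}
    assert consensus_targets(disjoint) == []


def test_consensus_monotone_in_quorum():
    sets = {
        "a": [_site("a", 10, 18), _site("a", 40, 46)],
        "b": [_site("b", 14, 22)],
        "c": [_site("c", 16, 24), _site("c", 41, 47)],
    }
    for k in (3, 2):
        high = consensus_targets(sets, k_required=k)
        low = consensus_targets(sets, k_required=k - 1)
        for site in high:
            assert any(
                s.mirna == site.mirna and s.transcript == site.transcript
                and s.start <= site.start and site.end <= s.end
                for s in low
            )


# ---------------------------------------------------------------------------
# Score filters


def _pred_frame():
    return pd.DataFrame(
        {
            "mirna": ["m"] * 6,
            "transcript": ["t"] * 6,
            "start": [0] * 6,
            "end": [6] * 6,
            "source": ["miranda", "miranda", "targetspy", "targetspy", "pita", "pita"],
            "score": [160.0, 140.0, 0.995, 0.5, np.nan, np.nan],
            "energy": [-25.0, -25.0, -25.0, -25.0, -25.0, -15.0],
        }
    )


def test_score_filter_matches_manual_application():
    df = _pred_frame()
    df.loc[df["source"] == "pita", "score"] = 0.0  # pita has no score gate
    kept = apply_score_filters(df)
    # manual: miranda needs >=150, targetspy >=0.99, everything needs energy <= -20
    assert kept["source"].tolist() == ["miranda", "targetspy", "pita"]
    assert (kept["energy"] <= -20).all()


def test_energy_gate_dominates_and_missing_score_rejected():
    df = pd.DataFrame(
        {"mirna": ["m"], "transcript": ["t"], "start": [0], "end": [6],
         "source": ["miranda"], "score": [999.0], "energy": [-15.0]}
    )
    assert apply_score_filters(df).empty
    df_missing = df.assign(energy=[-25.0], score=[np.nan])
    with pytest.raises(ValidationError):
        apply_score_filters(df_missing)


# ---------------------------------------------------------------------------
# Sponges


def test_one_mrna_two_lncrnas_gives_two_triples(rng):
    expr = pd.DataFrame(rng.normal(10, 1, size=(3, 10)), index=["lncA", "lncB", "mr1"])
    lnc_sites = [TargetSite("mir-x", "lncA", "full", 0, 8, "8mer"),
                 TargetSite("mir-x", "lncB", "full", 0, 8, "8mer")]
    mr_sites = [TargetSite("mir-x", "mr1", "utr3", 0, 8, "8mer")]
    triples = find_sponge_candidates(lnc_sites, mr_sites, expr)
    assert {(t.lncrna, t.mrna, t.mirna) for t in triples} == {
        ("lncA", "mr1", "mir-x"), ("lncB", "mr1", "mir-x")
    }
    assert find_sponge_candidates(lnc_sites, [], expr) == []


def test_planted_sponges_recovered_exactly(genome, panels):
    records, seqs, truth = genome
    *_, netmat = panels
    utr3s = transcript_utr3s(seqs, truth.transcripts)
    sites = scan_transcriptome(truth.mirna_seqs, seqs, truth.transcripts, utr3s, min_class="8mer")
    lnc = [s for s in sites if truth.transcripts[s.transcript] == "lncRNA"]
    mr = [s for s in sites if truth.transcripts[s.transcript] == "mRNA"]
    triples = find_sponge_candidates(lnc, mr, netmat)

    planted = set()
    lnc_by_mir, mr_by_mir = {}, {}
    for mid, tid, _, _ in truth.seed_sites:
        bt = truth.transcripts[tid]
        (lnc_by_mir if bt == "lncRNA" else mr_by_mir).setdefault(mid, set()).add(tid)
    for mid in set(lnc_by_mir) & set(mr_by_mir):
        for l in lnc_by_mir[mid]:
            for m in mr_by_mir[mid]:
                planted.add((l, m, mid))
    got = {(t.lncrna, t.mrna, t.mirna) for t in triples}
    assert got == planted  # precision and recall both 1 on planted structure


def test_reciprocal_expression_filter():
    de = pd.DataFrame(
        {"call": ["up", "down", "up", "not-DE"]},
        index=["mir-a", "t1", "t2", "t3"],
    )
    pairs = [("mir-a", "t1"), ("mir-a", "t2"), ("mir-a", "t3"), ("mir-a", "absent")]
    assert reciprocal_expression_filter(de, pairs) == [("mir-a", "t1")]


# ---------------------------------------------------------------------------
# Pre-miRNA harboring


def test_premirna_exact_match_rules(rng):
    pre = "".join("ACGT"[i] for i in rng.integers(0, 4, size=64))
    host_bg = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
    host = host_bg[:120] + pre + host_bg[120:]
    hits = find_harbored_premirnas({"p1": pre}, {"L1": host})
    assert ("L1", "p1", 120, "+") in hits

    mutated = host[:150] + ("A" if host[150] != "A" else "C") + host[151:]
    assert find_harbored_premirnas({"p1": pre}, {"L1": mutated}) == []

    rc_host = host_bg[:60] + revcomp(pre) + host_bg[60:]
    assert ("L2", "p1", 60, "-") in find_harbored_premirnas({"p1": pre}, {"L2": rc_host})

    assert find_harbored_premirnas({"p1": pre}, {"tiny": "ACGT"}) == []


def test_premirna_finder_matches_naive_oracle(genome):
    _, seqs, truth = genome
    lnc_seqs = {i: s for i, s in seqs.items() if truth.transcripts[i] == "lncRNA"}
    got = set(find_harbored_premirnas(truth.premirna_seqs, lnc_seqs))
    naive = set()
    for lid, host in lnc_seqs.items():
        for pid, pre in truth.premirna_seqs.items():
            for strand, q in (("+", pre), ("-", revcomp(pre))):
                for off in range(len(host) - len(q) + 1):
                    if host[off : off + len(q)] == q:
                        naive.add((lid, pid, off, strand))
    assert got == naive
    assert {(l, p, o, "+") for l, p, o in truth.premirna_hosts} <= got
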