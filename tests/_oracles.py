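"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (character-by-character scans, no
canonical index, no vectorisation) and shares no code path with the package
beyond the reverse-complement table.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def oracle_kmer_count(seq: str, query: str, circular: bool = False) -> int:
    """Count forward-strand windows equal to the query or its reverse complement."""
    k = len(query)
    scan = seq + seq[: k - 1] if circular else seq
    qrc = rc(query)
    n = 0
    for i in range(len(scan) - k + 1):
        w = scan[i : i + k]
        if "N" in w:
            continue
        if w == query or w == qrc:
            n += 1
    return n


def oracle_hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(1 for x, y in zip(a, b) if x != y)


def oracle_profile(site23: str, seq: str, circular: bool = False) -> dict[str, int]:
    """Naive double-strand tier counts for one CC-prefixed 23-mer site."""
    assert len(site23) == 23 and site23.startswith("CC")
    proto = site23[3:]
    prof = {
        "n_region1_cc": oracle_kmer_count(seq, "CC" + site23[2:10], circular),
        "n_region1_nearpam": oracle_kmer_count(seq, "CT" + site23[2:10], circular)
        + oracle_kmer_count(seq, "TC" + site23[2:10], circular),
        "n_region12_cc": oracle_kmer_count(seq, "CC" + site23[2:15], circular),
        "n_region12_nearpam": oracle_kmer_count(seq, "CT" + site23[2:15], circular)
        + oracle_kmer_count(seq, "TC" + site23[2:15], circular),
        "n_exact23": oracle_kmer_count(seq, site23, circular),
        "n_mm1": 0,
        "n_mm2": 0,
        "n_mm3": 0,
        "n_mm4": 0,
    }
    for strand_seq in (seq, rc(seq)):
        scan = strand_seq + strand_seq[:22] if circular else strand_seq
        for i in range(len(scan) - 22):
            w = scan[i : i + 23]
            if "N" in w or w[:2] not in ("CC", "CT", "TC"):
                continue
            d = oracle_hamming(w[3:], proto)
            if 1 <= d <= 4:
                prof[f"n_mm{d}"] += 1
    return prof


def oracle_cc_offsets(coding: str, window: int, max_offset: int) -> list[int]:
    """Offsets of CC dinucleotides within the window of a coding sequence."""
    return [
        i
        for i in range(min(window, max_offset) + 1)
        if coding[i : i + 2] == "CC"
    ]
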