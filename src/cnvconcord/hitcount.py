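"""Perfect and near-perfect probe occurrence counting in genome assemblies.

"Perfect alignment" is implemented as exact full-length string matching
of the probe (either strand) against each FASTA record; sub-100%
identity is a Hamming mismatch budget (no gaps). Matches never span
record boundaries, overlapping occurrences all count, and a position
matching in both orientations (palindromic probe) counts once. ``N``
never matches anything, on either side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from ._seq import revcomp
from .exceptions import ConfigError, DataError

#: canonical assembly order: {species A, species B} x {long-read, short-read}
ASSEMBLY_IDS = ("a_long", "a_short", "b_long", "b_short")


@dataclass(frozen=True)
class MatchParams:
    """Matching stringency. ``max_mismatches=0`` is the 100%-identity filter."""

    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ConfigError("max_mismatches must be >= 0")

    def identity_percent(self, probe_length: int) -> float:
        return 100.0 * (1.0 - self.max_mismatches / probe_length)


def _as_records(genome) -> list[str]:
    if isinstance(genome, str):
        return [genome]
    if isinstance(genome, Mapping):
        return list(genome.values())
    if hasattr(genome, "records"):  # synthio.Genome
        return list(genome.records().values())
    return list(genome)


def _exact_positions(seq: str, pat: str) -> set[int]:
    if "N" in pat:
        return set()
    out, i = set(), seq.find(pat)
    while i != -1:
        out.add(i)
        i = seq.find(pat, i + 1)
    return out


def _mismatches_leq(seq: str, start: int, pat: str, k: int) -> bool:
    budget = k
    for i, c in enumerate(pat):
        g = seq[start + i]
        if g != c or c == "N":
            budget -= 1
            if budget < 0:
                return False
    return True


def _approx_positions(seq: str, pat: str, k: int) -> set[int]:
    """Hamming matches via pigeonhole seeding: one of k+1 chunks is exact."""
    m, n = len(pat), len(seq)
    if m > n:
        return set()
    bounds = [(i * m // (k + 1), (i + 1) * m // (k + 1)) for i in range(k + 1)]
    cand: set[int] = set()
    for lo, hi in bounds:
        sub = pat[lo:hi]
        if "N" in sub:
            continue  # an exact chunk cannot contain N
        j = seq.find(sub)
        while j != -1:
            start = j - lo
            if 0 <= start <= n - m:
                cand.add(start)
            j = seq.find(sub, j + 1)
    return {s for s in cand if _mismatches_leq(seq, s, pat, k)}


def count_occurrences(probe: str, genome, params: MatchParams | None = None) -> int:
    """Number of distinct (record, start) positions matching probe or its
    reverse complement with at most ``params.max_mismatches`` mismatches."""
    if not probe:
        raise DataError("empty probe sequence")
    params = params or MatchParams()
    k = params.max_mismatches
    if k >= len(probe):
        raise ConfigError("max_mismatches must be smaller than the probe length")
    rc = revcomp(probe)
    total = 0
    for seq in _as_records(genome):
        if len(seq) < len(probe):
            continue
        if k == 0:
            pos = _exact_positions(seq, probe)
            if rc != probe:
                pos |= _exact_positions(seq, rc)
        else:
            pos = _approx_positions(seq, probe, k)
            if rc != probe:
                pos |= _approx_positions(seq, rc, k)
        total += len(pos)
    return total


def build_hit_table(
    probeset: pd.DataFrame,
    assemblies: Mapping[str, object],
    params: MatchParams | None = None,
) -> pd.DataFrame:
    """Per-probe occurrence counts in each of the four assemblies.

    ``assemblies`` maps the ids in :data:`ASSEMBLY_IDS` to genomes
    (str, mapping of records, or synthio.Genome). Returns a complete
    probe_id-indexed table with one count column per assembly.
    """
    params = params or MatchParams()
    missing = [a for a in ASSEMBLY_IDS if a not in assemblies]
    if missing:
        raise DataError(f"missing assemblies: {missing}")
    ids = probeset["probe_id"]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise DataError(f"duplicate probe id {dup!r}")
    records = {a: _as_records(assemblies[a]) for a in ASSEMBLY_IDS}
    data = {
        a: [count_occurrences(s, records[a], params) for s in probeset["seq"]]
        for a in ASSEMBLY_IDS
    }
    return pd.DataFrame(data, index=pd.Index(ids, name="probe_id"))


def filter_universal(table: pd.DataFrame) -> pd.DataFrame:
    """Probes with at least one perfect hit in each of the four assemblies."""
    return table[(table[list(ASSEMBLY_IDS)] >= 1).all(axis=1)]


def classify_multicopy(filtered: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
    """Split the universal set into (single-copy, multi-copy) probe ids.

    Multi-copy: two or more hits in at least one assembly.
    """
    multi = (filtered[list(ASSEMBLY_IDS)] >= 2).any(axis=1)
    return filtered.index[~multi], filtered.index[multi]


def identity_sweep(
    probeset: pd.DataFrame,
    assemblies: Mapping[str, object],
    max_mismatch_list: Iterable[int],
) -> dict[int, pd.DataFrame]:
    """Hit tables across a sweep of mismatch budgets.

    Probes are fixed to the universal set defined at the perfect-match
    level (each probe still needs >= 1 perfect hit in all four
    assemblies); counts are then recomputed at each budget and are
    non-decreasing in the budget.
    """
    base = build_hit_table(probeset, assemblies, MatchParams(0))
    universal_ids = filter_universal(base).index
    sub = probeset[probeset["probe_id"].isin(universal_ids)]
    out: dict[int, pd.DataFrame] = {}
    for k in sorted(set(int(k) for k in max_mismatch_list)):
        if k == 0:
            out[0] = base.loc[universal_ids]
        else:
            out[k] = build_hit_table(sub, assemblies, MatchParams(k))
    return out
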