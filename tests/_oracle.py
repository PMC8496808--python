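"""Independent brute-force oracles used to validate the fast paths.

Deliberately naive: enumerate every (record, position, orientation) and
count mismatches character by character. Must never share code with the
implementation under test.
"""

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_revcomp(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def brute_count(probe: str, records, max_mismatches: int = 0) -> int:
    """Count distinct start positions matching probe or its reverse
    complement with <= max_mismatches mismatches; N never matches."""
    if isinstance(records, str):
        records = [records]
    elif isinstance(records, dict):
        records = list(records.values())
    rc = brute_revcomp(probe)
    pats = [probe] if rc == probe else [probe, rc]
    total = 0
    for seq in records:
        for start in range(len(seq) - len(probe) + 1):
            for pat in pats:
                mm = 0
                for i in range(len(pat)):
                    a, b = seq[start + i], pat[i]
                    if a != b or a == "N" or b == "N":
                        mm += 1
                        if mm > max_mismatches:
                            break
                if mm <= max_mismatches:
                    total += 1
                    break  # a position counts once even if both strands match
    return total
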