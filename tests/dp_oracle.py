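"""Independent quadratic-DP local aligner used as a test oracle.

Plain-Python affine-gap Smith–Waterman (Gotoh) with full traceback,
deliberately sharing no code with the package's aligner.  Scoring
convention matches the package contract: a gap of length L costs
``gap_open + L * gap_extend``; N never matches; identity is computed
over aligned columns with gap columns counted as mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

NEG = float("-inf")


@dataclass
class OracleAlignment:
    score: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    identities: int
    columns: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.identities / self.columns if self.columns else 0.0


def smith_waterman(query: str, subject: str, match: int = 1,
                   mismatch: int = -2, gap_open: int = 5,
                   gap_extend: int = 2) -> Optional[OracleAlignment]:
    """Optimal local alignment, or None when the best score is <= 0."""
    n, m = len(query), len(subject)
    open_cost = gap_open + gap_extend

    def sub(a: str, b: str) -> int:
        return match if (a == b and a != "N") else mismatch

    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (subject ins)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject
    best, best_pos = 0.0, None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + sub(query[i - 1], subject[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best, best_pos = H[i][j], (i, j)
    if best_pos is None:
        return None
    # Traceback through the three-state lattice.
    i, j = best_pos
    state = "H"
    identities = columns = 0
    q_end, s_end = i, j
    while True:
        if state == "H":
            if H[i][j] == 0.0:
                break
            diag = H[i - 1][j - 1] + sub(query[i - 1], subject[j - 1])
            if H[i][j] == diag:
                columns += 1
                if query[i - 1] == subject[j - 1] and query[i - 1] != "N":
                    identities += 1
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            if E[i][j] == H[i][j - 1] - open_cost:
                j -= 1
                state = "H"
            else:
                j -= 1
        else:
            columns += 1
            if F[i][j] == H[i - 1][j] - open_cost:
                i -= 1
                state = "H"
            else:
                i -= 1
    return OracleAlignment(score=best, q_start=i, q_end=q_end,
                           s_start=j, s_end=s_end,
                           identities=identities, columns=columns)


_RC = str.maketrans("ACGTN", "TGCAN")


def best_local_both_strands(query: str, subject: str, **kw
                            ) -> Tuple[Optional[OracleAlignment], str]:
    """Best alignment over both subject strands; '+' wins ties."""
    fwd = smith_waterman(query, subject, **kw)
    rev = smith_waterman(query.translate(_RC)[::-1], subject, **kw)
    if rev is None or (fwd is not None and fwd.score >= rev.score):
        return fwd, "+"
    return rev, "-"
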