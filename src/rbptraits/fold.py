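"""Minimum free energy of nested RNA secondary structures.

The built-in engine is a weighted base-pair-maximization dynamic program
(Nussinov-style): allowed pairs score GC/CG = -3, AU/UA = -2, GU/UG = -1,
hairpin loops must contain at least ``min_loop`` (default 3) unpaired bases,
pseudoknots are excluded, and the structure energy is the sum of its pair
energies.  The MFE is the minimum of this energy over all nested structures,
hence always <= 0 (the empty structure scores 0).

This model deliberately has no stacking, dangles or loop entropies; it ranks
self-complementary GC-rich leaders as more structured than unstructured ones,
which is what the downstream 5'UTR comparisons need, and it is exactly
checkable against exhaustive enumeration.  A thermodynamic engine (e.g.
ViennaRNA's RNAfold) can be plugged in through the ``engine`` argument of
the feature-level functions.
"""

from __future__ import annotations

import numpy as np

PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}

_ALPHABET = set("ACGU")


class FoldError(ValueError):
    pass


def _clean(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - _ALPHABET
    if bad:
        raise FoldError(f"invalid characters in RNA sequence: {sorted(bad)}")
    return s


def fold_mfe(seq: str, min_loop: int = 3) -> float:
    """MFE of the best nested structure under the pair-sum energy model.

    O(n^3) time, O(n^2) memory.  T is auto-converted to U; any other
    non-ACGU character raises.
    """
    s = _clean(seq)
    n = len(s)
    if n == 0:
        return 0.0
    pair = np.zeros((n, n))
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            pair[i, j] = PAIR_ENERGY.get((s[i], s[j]), np.inf)

    E = np.zeros((n + 1, n + 1))
    # E[i][j] holds the MFE of s[i:j] (half-open); spans grow outward
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span  # subsequence s[i:j], last index j-1
            best = E[i + 1, j]  # i unpaired
            v = E[i, j - 1]  # j-1 unpaired
            if v < best:
                best = v
            e = pair[i, j - 1]
            if np.isfinite(e):
                v = E[i + 1, j - 1] + e
                if v < best:
                    best = v
            # bifurcation: i pairs with some k in (i, j-1)
            if span > 2 * (min_loop + 2) - 1:
                ks = np.arange(i + min_loop + 1, j - 1)
                if ks.size:
                    pe = pair[i, ks]
                    finite = np.isfinite(pe)
                    if finite.any():
                        ks = ks[finite]
                        v = np.min(E[i + 1, ks] + pe[finite] + E[ks + 1, j])
                        if v < best:
                            best = v
            E[i, j] = best
    return float(E[0, n])


def enumerate_mfe(seq: str, min_loop: int = 3) -> float:
    """Exhaustive minimum over all nested structures (oracle; exponential).

    Only practical for short sequences (length <= ~14).
    """
    s = _clean(seq)

    def rec(i: int, j: int) -> float:
        # minimum energy of s[i:j]
        if j - i < min_loop + 2:
            return 0.0
        best = rec(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j):
            e = PAIR_ENERGY.get((s[i], s[k]))
            if e is None:
                continue
            cand = e + rec(i + 1, k) + rec(k + 1, j)
            if cand < best:
                best = cand
        return best

    return float(rec(0, len(s)))


def fold_mfe_rnafold(seq: str) -> float:
    """MFE from ViennaRNA's RNAfold CLI (thermodynamic, kcal/mol).

    Drop-in alternative engine for the feature-level comparisons; requires
    the ``RNAfold`` executable on PATH.
    """
    import re
    import subprocess

    s = _clean(seq)
    out = subprocess.run(
        ["RNAfold", "--noPS"], input=s + "\n", capture_output=True,
        text=True, check=True,
    ).stdout
    match = re.search(r"\(\s*(-?\d+\.?\d*)\s*\)\s*$", out.strip())
    if match is None:
        raise FoldError(f"could not parse RNAfold output: {out!r}")
    return float(match.group(1))


def normalized_mfe(seq: str, engine=fold_mfe) -> float:
    """MFE divided by sequence length (energy per nucleotide, <= 0)."""
    s = _clean(seq)
    if len(s) == 0:
        raise FoldError("empty sequence")
    return engine(s) / len(s)
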