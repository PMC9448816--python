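"""Spacer secondary-structure minimum free energy (MFE).

A spacer that folds on itself is less available for loading and target
pairing, so the predicted folding free energy of the 20-nt spacer (read as
RNA) is a model feature.  The default engine is a dynamic-programming fold
under a deliberately simple, fully specified energy model:

* allowed pairs: Watson-Crick (A-U, G-C) and G-U wobble;
* every pair must enclose at least ``MIN_HAIRPIN`` = 3 unpaired bases;
* structure energy = sum of pair energies + a stacking bonus for every
  pair (i, j) whose inner neighbor (i+1, j-1) is also paired;
* no pseudoknots.

The model is additive over pairs and stacks, so the DP below computes the
exact minimum over all secondary structures — verifiable by exhaustive
enumeration at short lengths.  ViennaRNA (full Turner model, 37 °C) can be
swapped in with ``engine="vienna"``; its magnitudes differ but the sign and
ordering semantics are the same.
"""

from __future__ import annotations

import functools

#: pair formation energies (kcal/mol, negative = stabilizing), T read as U
PAIR_ENERGY: dict[frozenset, float] = {
    frozenset(("G", "C")): -2.1,
    frozenset(("A", "T")): -1.1,
    frozenset(("G", "T")): -0.6,
}

#: bonus for each coaxially stacked pair of adjacent base pairs
STACK_BONUS: float = -1.0

#: minimum number of unpaired bases enclosed by the innermost pair
MIN_HAIRPIN: int = 3

_INF = float("inf")


def pair_energy(a: str, b: str) -> float:
    """Energy of pairing bases ``a`` and ``b``; +inf if not pairable."""
    return PAIR_ENERGY.get(frozenset((a, b)), _INF)


def can_pair(a: str, b: str) -> bool:
    return frozenset((a, b)) in PAIR_ENERGY


def _mfe_builtin(seq: str) -> float:
    n = len(seq)
    if n < MIN_HAIRPIN + 2:
        return 0.0
    # E[i][j]: minimum energy of seq[i..j]; P[i][j]: minimum given (i,j) paired
    E = [[0.0] * n for _ in range(n)]
    P = [[_INF] * n for _ in range(n)]
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(n - span):
            j = i + span
            pe = pair_energy(seq[i], seq[j])
            if pe < _INF:
                interior = E[i + 1][j - 1] if j - 1 > i + 1 else 0.0
                best = interior
                if P[i + 1][j - 1] < _INF:
                    stacked = P[i + 1][j - 1] + STACK_BONUS
                    if stacked < best:
                        best = stacked
                P[i][j] = pe + best
            # j unpaired
            best = E[i][j - 1]
            # j paired with some k in [i, j - MIN_HAIRPIN - 1]
            for k in range(i, j - MIN_HAIRPIN):
                if P[k][j] < _INF:
                    left = E[i][k - 1] if k > i else 0.0
                    cand = left + P[k][j]
                    if cand < best:
                        best = cand
            E[i][j] = best
    return min(0.0, E[0][n - 1])


@functools.lru_cache(maxsize=200_000)
def _mfe_builtin_cached(seq: str) -> float:
    return _mfe_builtin(seq)


def _mfe_vienna(seq: str) -> float:
    import RNA  # optional engine; ViennaRNA python bindings

    rna = seq.replace("T", "U")
    _, energy = RNA.fold(rna)
    return min(0.0, float(energy))


def spacer_mfe(spacer: str, engine: str = "builtin", check_length: bool = False) -> float:
    """Minimum free energy (kcal/mol, ≤ 0) of the folded spacer.

    ``spacer`` is given in DNA letters; T is read as U.  Returns 0 when no
    favorable structure exists.
    """
    spacer = spacer.upper()
    if check_length and len(spacer) != 20:
        raise ValueError(f"spacer must be 20 nt, got {len(spacer)}")
    bad = set(spacer) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT symbols: {sorted(bad)}")
    if engine == "builtin":
        return _mfe_builtin_cached(spacer)
    if engine == "vienna":
        return _mfe_vienna(spacer)
    raise ValueError(f"unknown MFE engine {engine!r}")
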