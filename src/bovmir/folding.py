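"""Pseudoknot-free RNA secondary structure prediction by dynamic programming.

The energy model is a deliberately simple additive nearest-neighbour
surrogate, adequate for rank-ordering hairpin candidates rather than for
wet-lab-grade thermodynamics:

* each allowed base pair contributes a pairing energy
  (GC: -3.0, AU: -2.0, GU: -1.0 kcal/mol);
* a pair stacked directly on another pair (i+1, j-1 also paired) earns an
  additional stacking bonus of -1.0 kcal/mol, so contiguous helices are
  rewarded over isolated pairs;
* every hairpin loop (a pair enclosing no further pairs) costs
  3.0 + 0.25 * (loop_size - 3) kcal/mol, with loop_size >= 3 enforced;
* bulge/internal/multibranch loops carry no explicit penalty.

The total energy of a structure is the sum of these terms, and the
reported MFE is min(0, optimum) — the open chain is always available.
The same model can be evaluated on an explicit pair set, so the optimum is
checkable against exhaustive enumeration on short sequences.

An external folding backend (ViennaRNA's RNAfold binary) can be requested
behind the same interface when physical energies are wanted.
"""

from __future__ import annotations

import subprocess

import numpy as np

from .util import normalize_seq

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    def _jit(func):
        return _njit(cache=True)(func)

except Exception:  # pragma: no cover
    def _jit(func):
        return func

INF = 1.0e9
MIN_LOOP = 3
STACK_BONUS = -1.0
HAIRPIN_BASE = 3.0
HAIRPIN_PER_NT = 0.25

_PAIR_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "T"): -2.0,
    ("T", "A"): -2.0,
    ("G", "T"): -1.0,
    ("T", "G"): -1.0,
}


def pair_energy(a: str, b: str) -> float:
    """Energy of pairing bases a-b (DNA alphabet, U normalised to T);
    +inf when the pair is not allowed."""
    return _PAIR_ENERGY.get((a, b), INF)


def hairpin_penalty(loop_size: int) -> float:
    if loop_size < MIN_LOOP:
        return INF
    return HAIRPIN_BASE + HAIRPIN_PER_NT * (loop_size - MIN_LOOP)


def structure_energy(seq: str, pairs: set[tuple[int, int]]) -> float:
    """Evaluate the model on an explicit structure (0-based pair set).

    This is the model *definition*; the DP below must agree with the
    minimum of this function over all legal structures.
    """
    s = normalize_seq(seq)
    total = 0.0
    pairset = {tuple(sorted(p)) for p in pairs}
    for i, j in pairset:
        e = pair_energy(s[i], s[j])
        if e >= INF / 2 or j - i - 1 < MIN_LOOP:
            raise ValueError(f"illegal pair ({i}, {j}) in structure")
        total += e
        if (i + 1, j - 1) in pairset:
            total += STACK_BONUS
        if not any(i < k < l < j for k, l in pairset):
            total += hairpin_penalty(j - i - 1)
    return total


@_jit
def _fold_dp(e: np.ndarray, hp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fill V (energy with i,j paired) and Wp (best energy with >=1 pair)."""
    n = e.shape[0]
    V = np.full((n, n), INF)
    Wp = np.full((n, n), INF)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if e[i, j] < INF / 2:
                best_in = hp[j - i - 1]
                if V[i + 1, j - 1] < INF / 2:
                    cand = V[i + 1, j - 1] + STACK_BONUS
                    if cand < best_in:
                        best_in = cand
                if Wp[i + 1, j - 1] < best_in:
                    best_in = Wp[i + 1, j - 1]
                V[i, j] = e[i, j] + best_in
            best = Wp[i, j - 1]
            for k in range(i, j - MIN_LOOP):
                if V[k, j] < INF / 2:
                    left = 0.0
                    if k > i and Wp[i, k - 1] < 0.0:
                        left = Wp[i, k - 1]
                    cand = left + V[k, j]
                    if cand < best:
                        best = cand
            Wp[i, j] = best
    return V, Wp


def _traceback(s: str, e: np.ndarray, hp: np.ndarray,
               V: np.ndarray, Wp: np.ndarray) -> list[tuple[int, int]]:
    eps = 1e-7
    n = len(s)
    pairs: list[tuple[int, int]] = []
    stack: list[tuple[str, int, int]] = []
    if n > MIN_LOOP and Wp[0, n - 1] < -eps:
        stack.append(("Wp", 0, n - 1))
    while stack:
        state, i, j = stack.pop()
        if state == "V":
            pairs.append((i, j))
            inner = V[i, j] - e[i, j]
            if abs(inner - hp[j - i - 1]) < eps:
                continue
            if V[i + 1, j - 1] < INF / 2 and abs(inner - (V[i + 1, j - 1] + STACK_BONUS)) < eps:
                stack.append(("V", i + 1, j - 1))
                continue
            stack.append(("Wp", i + 1, j - 1))
        else:  # Wp
            if j - i <= MIN_LOOP:
                raise AssertionError("traceback reached an unpairable span")
            if abs(Wp[i, j] - Wp[i, j - 1]) < eps:
                stack.append(("Wp", i, j - 1))
                continue
            done = False
            for k in range(i, j - MIN_LOOP):
                if V[k, j] >= INF / 2:
                    continue
                left = 0.0
                use_left = False
                if k > i and Wp[i, k - 1] < -eps:
                    left = Wp[i, k - 1]
                    use_left = True
                if abs(Wp[i, j] - (left + V[k, j])) < eps:
                    stack.append(("V", k, j))
                    if use_left:
                        stack.append(("Wp", i, k - 1))
                    done = True
                    break
                # the bifurcation may also be optimal without the left part
                if k > i and abs(Wp[i, j] - V[k, j]) < eps:
                    stack.append(("V", k, j))
                    done = True
                    break
            if not done:
                raise AssertionError("traceback failed to reproduce the optimum")
    return pairs


def pairs_to_dotbracket(n: int, pairs: list[tuple[int, int]]) -> str:
    structure = ["."] * n
    for i, j in pairs:
        structure[i] = "("
        structure[j] = ")"
    return "".join(structure)


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 when unpaired), from dot-bracket."""
    table = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced structure string")
            j = stack.pop()
            table[i] = j
            table[j] = i
    if stack:
        raise ValueError("unbalanced structure string")
    return table


def fold_rna(seq: str, backend: str = "builtin") -> tuple[str, float]:
    """Fold a sequence; returns (dot-bracket structure, MFE in kcal/mol).

    MFE is <= 0 by construction (the open chain is a legal structure).
    """
    s = normalize_seq(seq)
    if not s or set(s) - set("ACGT"):
        raise ValueError(f"sequence contains non-ACGU characters: {seq!r}")
    if backend == "viennarna":
        return _fold_viennarna(seq)
    if backend != "builtin":
        raise ValueError(f"unknown folding backend {backend!r}")
    n = len(s)
    if n <= MIN_LOOP + 1:
        return "." * n, 0.0
    e = np.full((n, n), INF)
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            e[i, j] = pair_energy(s[i], s[j])
    hp = np.array([hairpin_penalty(k) if k >= MIN_LOOP else INF for k in range(n)])
    V, Wp = _fold_dp(e, hp)
    mfe = min(0.0, float(Wp[0, n - 1]))
    pairs = _traceback(s, e, hp, V, Wp)
    return pairs_to_dotbracket(n, pairs), mfe


def _fold_viennarna(seq: str) -> tuple[str, float]:  # pragma: no cover - thin wrapper
    rna = normalize_seq(seq).replace("T", "U")
    out = subprocess.run(
        ["RNAfold", "--noPS"], input=rna + "\n", capture_output=True, text=True, check=True
    )
    lines = out.stdout.strip().splitlines()
    structure, energy = lines[1].rsplit(" ", 1)
    structure = structure.strip()
    return structure, float(energy.strip("() "))


def compute_mfei(mfe: float, seq: str) -> tuple[float, float]:
    """Adjusted MFE (kcal/mol per 100 nt) and minimal folding energy index.

    AMFE = (-MFE / length) * 100;  MFEI = AMFE / GC-percent.
    """
    s = normalize_seq(seq)
    if not s:
        raise ValueError("empty sequence")
    if mfe > 0:
        raise ValueError("MFE must be <= 0")
    amfe = (-mfe / len(s)) * 100.0
    gc_pct = 100.0 * (s.count("G") + s.count("C")) / len(s)
    if gc_pct == 0:
        raise ValueError("MFEI undefined for zero GC content")
    return amfe, amfe / gc_pct
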