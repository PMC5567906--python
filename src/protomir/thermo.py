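"""RNA secondary-structure engines.

Two interchangeable engines provide single-sequence folding (dot-bracket
structure + minimum free energy) and two-strand duplex energies:

* ``ViennaEngine`` — nearest-neighbor thermodynamics via the ViennaRNA
  python bindings (``RNA.fold`` / ``RNA.duplexfold``).  Default when the
  bindings are importable.
* ``NussinovEngine`` — self-contained maximum base-pairing dynamic
  program (Watson-Crick + G·U, minimum hairpin loop 3) with a
  pair-count pseudo-energy of -1.0 kcal/mol per pair.  Intended for
  short sequences and as an engine-independent cross-check; O(n^3).

Energies are kcal/mol, more negative = more stable.  A "duplex" energy
>= 0 means no stabilising interaction.
"""

from __future__ import annotations

from functools import lru_cache

from ._seq import to_rna

_CAN_PAIR = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),
}

MIN_LOOP = 3


class NussinovEngine:
    """Maximum-pairing folder with a per-pair pseudo-energy."""

    name = "nussinov"

    def __init__(self, energy_per_pair: float = -1.0, min_loop: int = MIN_LOOP):
        self.energy_per_pair = energy_per_pair
        self.min_loop = min_loop

    def fold(self, seq: str) -> tuple[str, float]:
        s = _check_rna(seq)
        n = len(s)
        if n < 2:
            return "." * n, 0.0
        dp = [[0] * n for _ in range(n)]
        for span in range(self.min_loop + 1, n):
            for i in range(0, n - span):
                j = i + span
                best = dp[i + 1][j]  # i unpaired
                if (s[i], s[j]) in _CAN_PAIR:
                    best = max(best, dp[i + 1][j - 1] + 1)
                for k in range(i + self.min_loop + 1, j):
                    if (s[i], s[k]) in _CAN_PAIR:
                        cand = dp[i + 1][k - 1] + 1 + (dp[k + 1][j] if k + 1 <= j else 0)
                        if cand > best:
                            best = cand
                dp[i][j] = best
        struct = ["."] * n
        self._traceback(s, dp, 0, n - 1, struct)
        pairs = struct.count("(")
        return "".join(struct), pairs * self.energy_per_pair

    def _traceback(self, s, dp, i, j, struct) -> None:
        stack = [(i, j)]
        while stack:
            i, j = stack.pop()
            if j - i <= self.min_loop:
                continue
            if dp[i][j] == dp[i + 1][j]:
                stack.append((i + 1, j))
                continue
            for k in range(i + self.min_loop + 1, j + 1):
                if (s[i], s[k]) in _CAN_PAIR:
                    right = dp[k + 1][j] if k + 1 <= j else 0
                    if dp[i][j] == dp[i + 1][k - 1] + 1 + right:
                        struct[i], struct[k] = "(", ")"
                        stack.append((i + 1, k - 1))
                        if k + 1 <= j:
                            stack.append((k + 1, j))
                        break

    def duplex(self, seq1: str, seq2: str) -> float:
        """Pseudo-energy of the best hybrid: fold the linked pair, count
        only inter-strand pairs."""
        s1, s2 = _check_rna(seq1), _check_rna(seq2)
        linker = "X" * (self.min_loop + 1)
        s = s1 + linker + s2
        n, n1 = len(s), len(s1)
        dp = [[0] * n for _ in range(n)]
        for span in range(self.min_loop + 1, n):
            for i in range(0, n - span):
                j = i + span
                best = dp[i + 1][j]
                for k in range(i + self.min_loop + 1, j + 1):
                    # inter-strand pairs only: i on strand 1, k on strand 2
                    if i < n1 and k >= n1 + len(linker) and (s[i], s[k]) in _CAN_PAIR:
                        inner = dp[i + 1][k - 1] if k - 1 >= i + 1 else 0
                        right = dp[k + 1][j] if k + 1 <= j else 0
                        cand = inner + 1 + right
                        if cand > best:
                            best = cand
                dp[i][j] = best
        return dp[0][n - 1] * self.energy_per_pair


class ViennaEngine:
    """Nearest-neighbor MFE folding through the ViennaRNA bindings."""

    name = "vienna"

    def __init__(self):
        import RNA  # deferred so the engine is optional

        self._RNA = RNA

    def fold(self, seq: str) -> tuple[str, float]:
        s = _check_rna(seq)
        struct, mfe = self._RNA.fold(s)
        return struct, float(mfe)

    def duplex(self, seq1: str, seq2: str) -> float:
        d = self._RNA.duplexfold(_check_rna(seq1), _check_rna(seq2))
        return float(d.energy)


def _check_rna(seq: str) -> str:
    if len(seq) == 0:
        raise ValueError("empty sequence")
    s = to_rna(seq)
    if not set(s) <= set("ACGU"):
        raise ValueError(f"invalid nucleotide alphabet in {seq[:30]!r}")
    return s


@lru_cache(maxsize=None)
def _default_engine_cls():
    try:
        import RNA  # noqa: F401

        return ViennaEngine
    except ImportError:
        return NussinovEngine


def get_engine(name: str = "auto"):
    """Return a fold engine: 'vienna', 'nussinov', or 'auto' (best available)."""
    if name == "vienna":
        return ViennaEngine()
    if name == "nussinov":
        return NussinovEngine()
    if name == "auto":
        return _default_engine_cls()()
    raise ValueError(f"unknown fold engine {name!r}")


def pair_table(structure: str) -> list[int | None]:
    """Map each position to its pairing partner (0-based), None if unpaired."""
    table: list[int | None] = [None] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced structure string")
            j = stack.pop()
            table[i], table[j] = j, i
    if stack:
        raise ValueError("unbalanced structure string")
    return table
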