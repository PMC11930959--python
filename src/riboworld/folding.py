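"""RNA secondary-structure backends and loop decomposition.

A replicator's phenotype is derived from the minimum-free-energy (MFE)
secondary structure of its sequence.  Production runs use the ViennaRNA
engine through its Python bindings; a self-contained Nussinov-style
base-pair-maximisation backend is provided so that every part of the
package (and its test suite) can run without the compiled engine.

Only two loop kinds are considered motif-bearing: hairpin (terminal)
loops and interior loops, where bulges count as interior loops with one
empty side.  Multiloops and exterior unpaired bases carry no motifs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

RNA_BASES = "ACGU"
_BASE_SET = frozenset(RNA_BASES)

#: minimum sequence length that can accommodate a hairpin (1 bp stem + 3 nt loop
#: + closing bases); shorter sequences are treated as open chains
MIN_FOLDABLE_LENGTH = 8

#: minimum number of unpaired bases enclosed by a hairpin-closing pair
MIN_HAIRPIN_LOOP = 3

#: pairs accepted by the fallback backend (Watson-Crick + wobble)
_CAN_PAIR = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

#: surrogate free energy per base pair used by the fallback backend (kcal/mol)
FALLBACK_ENERGY_PER_PAIR = -2.0


class FoldingError(ValueError):
    """Raised for invalid sequences or malformed dot-bracket structures."""


@dataclass(frozen=True)
class SecondaryStructure:
    """An MFE secondary structure in Vienna dot-bracket notation.

    ``mfe`` is the free energy in kcal/mol; it is 0.0 exactly when the
    structure is the open chain (no base pairs), and negative otherwise.
    """

    dot_bracket: str
    mfe: float

    def __post_init__(self) -> None:
        depth = 0
        for ch in self.dot_bracket:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise FoldingError("unbalanced dot-bracket structure")
            elif ch != ".":
                raise FoldingError(f"invalid dot-bracket character {ch!r}")
        if depth != 0:
            raise FoldingError("unbalanced dot-bracket structure")

    @property
    def n_pairs(self) -> int:
        return self.dot_bracket.count("(")

    def pair_table(self) -> dict[int, int]:
        """Map each paired position to its partner (both directions)."""
        stack: list[int] = []
        pairs: dict[int, int] = {}
        for i, ch in enumerate(self.dot_bracket):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                j = stack.pop()
                pairs[i] = j
                pairs[j] = i
        return pairs


@dataclass(frozen=True)
class Loop:
    """A motif-eligible loop: hairpin or interior (bulges included).

    ``unpaired_positions`` lists the 0-based sequence indices of the
    loop's unpaired bases in 5'->3' order; for interior loops the 5'
    side precedes the 3' side in the concatenation.
    """

    kind: str  # "hairpin" | "interior"
    unpaired_positions: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.unpaired_positions)

    def sequence(self, seq: str) -> str:
        return "".join(seq[i] for i in self.unpaired_positions)


def validate_sequence(sequence: str) -> None:
    if not sequence:
        raise FoldingError("empty sequence")
    if not _BASE_SET.issuperset(sequence):
        bad = sorted(set(sequence) - _BASE_SET)
        raise FoldingError(f"invalid RNA bases {bad}; alphabet is A/C/G/U")


class FoldingBackend(Protocol):
    """Contract for pluggable MFE engines (deterministic per sequence)."""

    name: str

    def fold(self, sequence: str) -> SecondaryStructure: ...


class ViennaBackend:
    """MFE folding through the ViennaRNA Python bindings (default model)."""

    name = "vienna"

    def __init__(self) -> None:
        import RNA  # deferred: the engine is optional

        self._rna = RNA

    def fold(self, sequence: str) -> SecondaryStructure:
        validate_sequence(sequence)
        db, mfe = self._rna.fold(sequence)
        if "(" not in db:
            mfe = 0.0  # open-chain convention
        return SecondaryStructure(db, float(mfe))


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_CAN_PAIR_TABLE = np.zeros((4, 4), dtype=bool)
for _a, _b in _CAN_PAIR:
    _CAN_PAIR_TABLE[_BASE_CODE[_a], _BASE_CODE[_b]] = True


def _nussinov_pairs_plain(codes: np.ndarray) -> np.ndarray:
    """DP fill + traceback over nested pairings; returns partner array.

    ``best[i][j]`` is the maximum pair count of the half-open interval
    ``[i, j)``.  Traceback is deterministic: pairings of the leftmost
    base are tried 5'->3' before leaving it unpaired.
    """
    n = codes.shape[0]
    canp = _CAN_PAIR_TABLE
    best = np.zeros((n + 2, n + 1), dtype=np.int32)
    min_span = MIN_HAIRPIN_LOOP + 2
    for span in range(min_span, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            b = best[i + 1, j]
            ks = np.nonzero(canp[codes[i], codes[i + MIN_HAIRPIN_LOOP + 1 : j]])[0]
            if ks.size:
                ks = ks + i + MIN_HAIRPIN_LOOP + 1
                cand = 1 + best[i + 1, ks] + best[ks + 1, j]
                b = max(b, int(cand.max()))
            best[i, j] = b
    partner = np.full(n, -1, dtype=np.int32)
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        while j - i >= min_span and best[i, j] > 0:
            paired = False
            for k in range(i + MIN_HAIRPIN_LOOP + 1, j):
                if (
                    canp[codes[i], codes[k]]
                    and 1 + best[i + 1, k] + best[k + 1, j] == best[i, j]
                ):
                    partner[i] = k
                    partner[k] = i
                    stack.append((k + 1, j))
                    j = k
                    i = i + 1
                    paired = True
                    break
            if not paired:
                i += 1
    return partner


_nussinov_pairs_jit = None


def _get_jit_kernel():
    """Compile the numba twin of the plain DP on first use (optional)."""
    global _nussinov_pairs_jit
    if _nussinov_pairs_jit is not None:
        return _nussinov_pairs_jit
    try:
        from numba import njit
    except ImportError:
        _nussinov_pairs_jit = False
        return False

    @njit(cache=False)
    def kernel(codes, canp):  # pragma: no cover - exercised via the backend
        n = codes.shape[0]
        best = np.zeros((n + 2, n + 1), dtype=np.int32)
        min_span = MIN_HAIRPIN_LOOP + 2
        for span in range(min_span, n + 1):
            for i in range(0, n - span + 1):
                j = i + span
                b = best[i + 1, j]
                for k in range(i + MIN_HAIRPIN_LOOP + 1, j):
                    if canp[codes[i], codes[k]]:
                        v = 1 + best[i + 1, k] + best[k + 1, j]
                        if v > b:
                            b = v
                best[i, j] = b
        partner = np.full(n, -1, dtype=np.int32)
        stack_i = np.empty(n + 1, dtype=np.int64)
        stack_j = np.empty(n + 1, dtype=np.int64)
        stack_i[0] = 0
        stack_j[0] = n
        depth = 1
        while depth > 0:
            depth -= 1
            i = stack_i[depth]
            j = stack_j[depth]
            while j - i >= min_span and best[i, j] > 0:
                paired = False
                for k in range(i + MIN_HAIRPIN_LOOP + 1, j):
                    if (
                        canp[codes[i], codes[k]]
                        and 1 + best[i + 1, k] + best[k + 1, j] == best[i, j]
                    ):
                        partner[i] = k
                        partner[k] = i
                        stack_i[depth] = k + 1
                        stack_j[depth] = j
                        depth += 1
                        j = k
                        i = i + 1
                        paired = True
                        break
                if not paired:
                    i += 1
        return partner

    _nussinov_pairs_jit = kernel
    return kernel


class NussinovBackend:
    """Base-pair maximisation with a surrogate energy of -2 kcal/mol per pair.

    Dynamic programming over nested pairings (min hairpin loop of 3
    unpaired bases, Watson-Crick + G:U wobble pairs) with a fixed
    traceback order (pairings tried 5'->3' before leaving a base
    unpaired), so results are deterministic.  A numba-compiled twin of
    the same DP is used when available; both paths produce identical
    structures.
    """

    name = "nussinov"

    def __init__(self, use_numba: bool | None = None) -> None:
        if use_numba is None:
            use_numba = bool(_get_jit_kernel())
        elif use_numba and not _get_jit_kernel():
            raise RuntimeError("numba is not importable; cannot use the jit kernel")
        self._use_numba = use_numba

    def fold(self, sequence: str) -> SecondaryStructure:
        validate_sequence(sequence)
        codes = np.frombuffer(
            sequence.encode().translate(bytes.maketrans(b"ACGU", bytes([0, 1, 2, 3]))),
            dtype=np.uint8,
        ).astype(np.int64)
        if self._use_numba:
            partner = _get_jit_kernel()(codes, _CAN_PAIR_TABLE)
        else:
            partner = _nussinov_pairs_plain(codes)
        db = np.full(len(sequence), ".", dtype="U1")
        opened = partner > np.arange(len(sequence))
        closed = (partner >= 0) & ~opened
        db[opened] = "("
        db[closed] = ")"
        n_pairs = int(opened.sum())
        return SecondaryStructure("".join(db), FALLBACK_ENERGY_PER_PAIR * n_pairs)


_OPEN_CACHE: dict[int, SecondaryStructure] = {}


class Folder:
    """Caching front-end over a folding backend.

    Adds the open-chain rule for sequences shorter than
    :data:`MIN_FOLDABLE_LENGTH` (no hairpin fits, so they are treated as
    unfoldable: mfe 0, no loops) and memoises results by exact sequence.
    """

    def __init__(self, backend: FoldingBackend | str = "auto") -> None:
        if isinstance(backend, str):
            backend = get_backend(backend)
        self.backend = backend
        self._cache: dict[str, SecondaryStructure] = {}

    def fold(self, sequence: str) -> SecondaryStructure:
        hit = self._cache.get(sequence)
        if hit is not None:
            return hit
        validate_sequence(sequence)
        if len(sequence) < MIN_FOLDABLE_LENGTH:
            n = len(sequence)
            ss = _OPEN_CACHE.get(n)
            if ss is None:
                ss = _OPEN_CACHE[n] = SecondaryStructure("." * n, 0.0)
        else:
            ss = self.backend.fold(sequence)
        self._cache[sequence] = ss
        return ss

    @property
    def cache_size(self) -> int:
        return len(self._cache)


def vienna_available() -> bool:
    try:
        import RNA  # noqa: F401
    except ImportError:
        return False
    return True


def get_backend(name: str = "auto") -> FoldingBackend:
    """Resolve a backend by name: "vienna", "nussinov" or "auto".

    "auto" prefers the ViennaRNA engine and falls back to the built-in
    Nussinov backend when the bindings are not importable.
    """
    if name == "auto":
        name = "vienna" if vienna_available() else "nussinov"
    if name == "vienna":
        return ViennaBackend()
    if name == "nussinov":
        return NussinovBackend()
    raise ValueError(f"unknown folding backend {name!r}")


def enumerate_loops(structure: SecondaryStructure) -> list[Loop]:
    """List every hairpin and interior loop of a structure exactly once.

    Loops are ordered by the position of their 5' closing pair.
    Interior loops concatenate the unpaired bases of the 5' side and
    then the 3' side; stacked pairs (zero unpaired bases) are not
    loops and are skipped.  Multiloops and exterior bases are not
    reported: they carry no activity motifs.
    """
    db = structure.dot_bracket
    pairs = structure.pair_table()
    loops: list[Loop] = []
    for i, ch in enumerate(db):
        if ch != "(":
            continue
        j = pairs[i]
        # scan the region enclosed by (i, j) for direct children
        children: list[tuple[int, int]] = []
        unpaired: list[int] = []
        k = i + 1
        while k < j:
            if db[k] == "(":
                children.append((k, pairs[k]))
                k = pairs[k] + 1
            else:
                unpaired.append(k)
                k += 1
        if not children:
            loops.append(Loop("hairpin", tuple(unpaired)))
        elif len(children) == 1 and unpaired:
            loops.append(Loop("interior", tuple(unpaired)))
        # stacked pair (one child, no unpaired) or multiloop: not motif-bearing
    return loops
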