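"""Per-replicator traits, activity motifs and mutagenic copying.

Every replicator trait is a deterministic function of the sequence and
its MFE structure:

* degradation probability ``P_deg = 0.1 + 0.8 * exp(d * dG_min)``,
  bounded in [0.1, 0.9];
* foldedness ``P_fold = 1 - 1/(1 + exp(-c * dG_min))``, clamped to 1
  for ``dG_min <= E_min`` (more stable folds spend more of their
  lifetime in the folded state);
* replicability ``R = g * (l + (1 - P_fold)) / (b1 + b2 * L)`` — the
  catalysis/replicability trade-off: a tightly folded strand is a
  better ribozyme but a worse template;
* enzymatic activities from structural motifs: a hairpin ("loop") or
  interior loop ("interloop") whose length exactly equals a rule's
  length, scored by how many of its three central bases match the
  rule's triplet (base activity 0/0.1/0.8/1), with a GC bonus from the
  flanking loop bases and a sub-additive penalty ``m**sigma`` when a
  strand carries m concurrent active motifs (cis-promiscuity).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .folding import Folder, Loop, SecondaryStructure, enumerate_loops

__all__ = [
    "ChemistryParams",
    "ActivityRule",
    "RuleTable",
    "MotifMatch",
    "ReplicatorTraits",
    "Replicator",
    "PairClass",
    "Chemistry",
    "degradation_rate",
    "folding_probability",
    "replicability",
    "match_motif",
    "motif_alpha",
    "strand_activities",
    "complement",
    "mutate_copy",
    "classify_pair",
    "load_rules",
]

#: base-activity lookup: number of central-triplet matches -> ā
BASE_ACTIVITY = (0.0, 0.1, 0.8, 1.0)

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


@dataclass(frozen=True)
class ChemistryParams:
    """Replicator-level parameters with their standard defaults.

    Units: energies in kcal/mol, times in arbitrary simulation units,
    mutation rates are per-base probabilities.
    """

    d: float = 0.2          # degradation slope
    c: float = 0.3          # foldedness scale
    E_min: float = -25.0    # empirical minimal folding energy (kcal/mol)
    g: float = 10.0         # replication rate scale
    l: float = 1.0          # replication rate offset
    b1: float = 0.75        # replication initialisation time
    b2: float = 0.005       # per-base elongation time
    xi: float = -0.3        # GC-modulation slope
    sigma: float = 1.1      # cis-promiscuity sub-additivity exponent
    p_sub: float = 0.05     # per-base substitution probability
    p_ins: float = 0.005    # per-base insertion probability
    p_del: float = 0.005    # per-base deletion probability

    def __post_init__(self) -> None:
        for name in ("p_sub", "p_ins", "p_del"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("g", "l", "b1", "b2", "sigma", "c", "d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ActivityRule:
    """One motif->activity rule: loop kind + exact length + central triplet."""

    id: int
    motif_kind: str  # "loop" (hairpin) | "interloop" (interior)
    loop_length: int
    triplet: str
    symbol: str = ""

    def __post_init__(self) -> None:
        if self.motif_kind not in ("loop", "interloop"):
            raise ValueError(f"unknown motif kind {self.motif_kind!r}")
        if self.loop_length % 2 != 1:
            raise ValueError("rule loop length must be odd (unique centre)")
        if len(self.triplet) != 3 or set(self.triplet) - set("ACGU"):
            raise ValueError(f"invalid triplet {self.triplet!r}")

    @property
    def loop_kind(self) -> str:
        """The folding-module loop kind this rule applies to."""
        return "hairpin" if self.motif_kind == "loop" else "interior"


def load_rules() -> tuple[ActivityRule, ...]:
    """Load the packaged 10-rule activity table."""
    text = resources.files("riboworld.data").joinpath("activity_rules.tsv").read_text()
    rules = []
    for line in text.strip().splitlines()[1:]:
        rid, kind, length, triplet, symbol = line.split("\t")
        rules.append(ActivityRule(int(rid), kind, int(length), triplet, symbol))
    return tuple(rules)


@dataclass(frozen=True)
class RuleTable:
    """The first ``A`` rules of an ordered rule list define the metabolism."""

    rules: tuple[ActivityRule, ...]
    A: int

    def __post_init__(self) -> None:
        if not 1 <= self.A <= len(self.rules):
            raise ValueError(f"A must be in [1, {len(self.rules)}], got {self.A}")

    @classmethod
    def default(cls, A: int) -> "RuleTable":
        return cls(load_rules(), A)

    @property
    def active_rules(self) -> tuple[ActivityRule, ...]:
        return self.rules[: self.A]

    def slot(self, rule_id: int) -> int:
        """Activity-vector index of a rule id (rule ids are 1-based)."""
        return rule_id - 1


@dataclass(frozen=True)
class MotifMatch:
    """A rule matched by one loop of a strand's MFE structure."""

    rule_id: int
    loop: Loop
    base_activity: float  # ā
    n_gc: int             # G/C count among non-central loop bases
    alpha: float          # α = ā + GC bonus


@dataclass(frozen=True)
class ReplicatorTraits:
    L: int
    dG_min: float
    P_deg: float
    P_fold: float
    R: float
    activities: np.ndarray  # length A, a_i >= 0
    matched_motifs: tuple[MotifMatch, ...]

    @property
    def is_active(self) -> bool:
        return bool(self.activities.any())

    @property
    def n_activities(self) -> int:
        """Number of distinct metabolic reactions this strand catalyses."""
        return int(np.count_nonzero(self.activities))

    @property
    def active_rule_ids(self) -> tuple[int, ...]:
        return tuple(sorted({m.rule_id for m in self.matched_motifs}))


@dataclass(frozen=True)
class Replicator:
    """An RNA strand with its cached structure-derived traits."""

    sequence: str
    structure: SecondaryStructure
    traits: ReplicatorTraits

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# trait formulas
# ---------------------------------------------------------------------------

def degradation_rate(dG_min: float, d: float = 0.2) -> float:
    """Per-update degradation probability, a sigmoid of the folding energy.

    ``P_deg = 0.1 + 0.8 * exp(d * dG_min)`` — 0.9 for the open chain
    (dG_min = 0), approaching the floor of 0.1 for very stable folds.
    """
    if dG_min > 0:
        warnings.warn("dG_min > 0 clamped to 0 for degradation rate", stacklevel=2)
        dG_min = 0.0
    return 0.1 + 0.8 * math.exp(d * dG_min)


def folding_probability(dG_min: float, c: float = 0.3, E_min: float = -25.0) -> float:
    """Fraction of lifetime spent in the MFE structure.

    ``P_fold = 1 - 1/(1 + exp(-c * dG_min))``, hard-clamped to 1 for
    ``dG_min <= E_min`` so that the empirically most stable sequences
    are always folded.  Monotone non-increasing in dG_min.
    """
    if dG_min <= E_min:
        return 1.0
    return 1.0 - 1.0 / (1.0 + math.exp(-c * dG_min))


def replicability(L: int, P_fold: float, params: ChemistryParams) -> float:
    """Replication rate ``R = g*(l + (1 - P_fold)) / (b1 + b2*L)``.

    Decreasing in both length (elongation time) and foldedness
    (only unfolded strands can serve as templates).
    """
    if L < 1:
        raise ValueError("sequence length must be >= 1")
    return params.g * (params.l + (1.0 - P_fold)) / (params.b1 + params.b2 * L)


def motif_alpha(base_activity: float, n_gc: int, xi: float = -0.3) -> float:
    """Net motif activity ``α = ā + 0.5/(1 + exp(n_GC * xi))``.

    With xi < 0 the GC term rises from 0.25 at n_GC = 0 toward the
    asymptotic bonus of 0.5 for GC-rich loops.
    """
    return base_activity + 0.5 / (1.0 + math.exp(n_gc * xi))


def match_motif(
    loop: Loop, loop_sequence: str, rule: ActivityRule
) -> tuple[float, int] | None:
    """Score one loop against one rule: ``(ā, n_GC)`` or None if no match.

    A match requires the loop kind and the *exact* loop length of the
    rule.  The three central bases of the 5'->3' concatenated loop
    sequence are compared position-wise with the rule triplet; n_GC
    counts G/C among the remaining (flanking) loop bases.
    """
    if loop.kind != rule.loop_kind:
        return None
    if loop.length != rule.loop_length:
        return None
    centre = loop.length // 2
    core = loop_sequence[centre - 1 : centre + 2]
    n_match = sum(a == b for a, b in zip(core, rule.triplet))
    flank = loop_sequence[: centre - 1] + loop_sequence[centre + 2 :]
    n_gc = sum(b in "GC" for b in flank)
    return BASE_ACTIVITY[n_match], n_gc


def strand_activities(
    matches: list[MotifMatch], P_fold: float, sigma: float, A: int, rules: RuleTable
) -> np.ndarray:
    """Fold motif matches into the activity vector ``a_1..a_A``.

    Only motifs with ā > 0 are active and count toward the concurrency
    m; each contributes ``P_fold * α / m**sigma`` to its rule's slot
    (a rule matched by several loops accumulates several such terms).
    """
    a = np.zeros(A)
    active = [m for m in matches if m.base_activity > 0]
    m = len(active)
    if m == 0:
        return a
    penalty = m**sigma
    for match in active:
        a[rules.slot(match.rule_id)] += P_fold * match.alpha / penalty
    return a


def complement(sequence: str) -> str:
    """Reverse complement with Watson-Crick pairing (A<->U, G<->C)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def mutate_copy(
    template: str, params: ChemistryParams, rng: np.random.Generator
) -> str:
    """One round of complementary, mutagenic copying.

    The template is walked 3'->5' so the copy grows 5'->3' as its
    reverse complement.  Per template base, independently: deletion
    with p_del (base skipped; no insertion/substitution applies to a
    skipped base), insertion with p_ins (a uniform random base added
    before the complementary base), substitution with p_sub (the
    complementary base replaced by a uniform random different base).
    The result may be empty (a failed replication).
    """
    comp = template.translate(_COMPLEMENT)[::-1]
    n = len(comp)
    if params.p_sub == 0.0 and params.p_ins == 0.0 and params.p_del == 0.0:
        return comp
    u = rng.random((n, 3))
    out: list[str] = []
    bases = "ACGU"
    for i, b in enumerate(comp):
        if u[i, 0] < params.p_del:
            continue
        if u[i, 1] < params.p_ins:
            out.append(bases[rng.integers(4)])
        if u[i, 2] < params.p_sub:
            b = "ACGU".replace(b, "")[rng.integers(3)]
        out.append(b)
    return "".join(out)


@dataclass(frozen=True)
class PairClass:
    """Classification of a strand together with its error-free complement.

    Flags can co-occur (a strand may be both cis- and trans-promiscuous);
    ``functional_parasite_complement`` marks an inactive strand paired
    with an active one.
    """

    strand_active_motifs: int
    complement_active_motifs: int
    specialist: bool
    cis_promiscuous: bool
    trans_promiscuous: bool
    real_parasite: bool
    functional_parasite_complement: bool

    @property
    def label(self) -> str:
        if self.real_parasite:
            return "real_parasite"
        tags = []
        if self.cis_promiscuous:
            tags.append("cis")
        if self.trans_promiscuous:
            tags.append("trans")
        if self.specialist:
            tags.append("specialist")
        return "+".join(tags) if tags else "active"


def classify_pair(strand: ReplicatorTraits, comp: ReplicatorTraits) -> PairClass:
    """Classify a strand/complement pair by their activity topology."""
    ns = len([m for m in strand.matched_motifs if m.base_activity > 0])
    nc = len([m for m in comp.matched_motifs if m.base_activity > 0])
    return PairClass(
        strand_active_motifs=ns,
        complement_active_motifs=nc,
        specialist=(ns + nc == 1),
        cis_promiscuous=(ns >= 2),
        trans_promiscuous=(ns >= 1 and nc >= 1),
        real_parasite=(ns == 0 and nc == 0),
        functional_parasite_complement=(ns >= 1 and nc == 0) or (nc >= 1 and ns == 0),
    )


# ---------------------------------------------------------------------------
# the shared chemistry context
# ---------------------------------------------------------------------------

class Chemistry:
    """Folding backend + rule table + parameters, with a trait registry.

    Traits are computed once per distinct sequence and cached; each
    distinct sequence receives a stable integer id.  The registry also
    maintains padded numpy trait arrays (row ``id + 1``; row 0 is the
    all-zero "empty" row) so that lattice code can gather degradation
    rates, replicabilities and activity vectors with fancy indexing.
    """

    def __init__(
        self,
        rules: RuleTable,
        params: ChemistryParams | None = None,
        folder: Folder | str = "auto",
    ) -> None:
        self.rules = rules
        self.params = params or ChemistryParams()
        self.folder = folder if isinstance(folder, Folder) else Folder(folder)
        self._ids: dict[str, int] = {}
        self._reps: list[Replicator] = []
        cap = 1024
        self._pdeg = np.zeros(cap)
        self._R = np.zeros(cap)
        self._act = np.zeros((cap, rules.A))

    # -- trait computation ----------------------------------------------

    def compute_traits(self, sequence: str) -> Replicator:
        """Fold a sequence and derive every trait (uncached path)."""
        ss = self.folder.fold(sequence)
        p = self.params
        P_deg = degradation_rate(ss.mfe, p.d)
        P_fold = folding_probability(ss.mfe, p.c, p.E_min)
        R = replicability(len(sequence), P_fold, p)
        matches: list[MotifMatch] = []
        for loop in enumerate_loops(ss):
            loop_seq = loop.sequence(sequence)
            for rule in self.rules.active_rules:
                scored = match_motif(loop, loop_seq, rule)
                if scored is None:
                    continue
                a_bar, n_gc = scored
                if a_bar > 0:
                    matches.append(
                        MotifMatch(rule.id, loop, a_bar, n_gc, motif_alpha(a_bar, n_gc, p.xi))
                    )
        acts = strand_activities(matches, P_fold, p.sigma, self.rules.A, self.rules)
        traits = ReplicatorTraits(
            L=len(sequence),
            dG_min=ss.mfe,
            P_deg=P_deg,
            P_fold=P_fold,
            R=R,
            activities=acts,
            matched_motifs=tuple(matches),
        )
        return Replicator(sequence, ss, traits)

    # -- registry ---------------------------------------------------------

    def replicator_id(self, sequence: str) -> int:
        """Stable id of a sequence, computing and caching traits on first use."""
        rid = self._ids.get(sequence)
        if rid is not None:
            return rid
        rep = self.compute_traits(sequence)
        rid = len(self._reps)
        self._reps.append(rep)
        self._ids[sequence] = rid
        row = rid + 1
        if row >= self._pdeg.shape[0]:
            self._grow()
        self._pdeg[row] = rep.traits.P_deg
        self._R[row] = rep.traits.R
        self._act[row] = rep.traits.activities
        return rid

    def _grow(self) -> None:
        cap = self._pdeg.shape[0] * 2
        for name in ("_pdeg", "_R"):
            new = np.zeros(cap)
            old = getattr(self, name)
            new[: old.shape[0]] = old
            setattr(self, name, new)
        new_act = np.zeros((cap, self.rules.A))
        new_act[: self._act.shape[0]] = self._act
        self._act = new_act

    def replicator(self, sequence: str) -> Replicator:
        return self._reps[self.replicator_id(sequence)]

    def replicator_by_id(self, rid: int) -> Replicator:
        return self._reps[rid]

    @property
    def n_registered(self) -> int:
        return len(self._reps)

    # padded trait views (index = id + 1; row 0 is the empty cell)
    @property
    def pdeg_padded(self) -> np.ndarray:
        return self._pdeg

    @property
    def R_padded(self) -> np.ndarray:
        return self._R

    @property
    def act_padded(self) -> np.ndarray:
        return self._act

    # -- replication ------------------------------------------------------

    def mutate_copy(self, template: str, rng: np.random.Generator) -> str:
        return mutate_copy(template, self.params, rng)

    def classify(self, rep: Replicator) -> PairClass:
        """Classify a replicator against its error-free complement."""
        comp = self.replicator(complement(rep.sequence))
        return classify_pair(rep.traits, comp.traits)
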