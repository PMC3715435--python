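"""Reconstruction and mechanistic classification of junction sequences.

Given an observed junction top strand and the two parental DSB ends, this
module enumerates every repair event (trimming, annealing, templated or
untemplated insertion) that reconstructs the junction exactly, ranks the
candidates by parsimony, and assigns the winner to a mechanistic repair
taxonomy:

Partially complementary 3' overhangs
    Type I    gap-filling-mediated: 1- or 2-nt terminal base pairing between
              the intact overhangs, remaining gaps filled by templated
              synthesis (the +CA/+AT signature)
    Type II   microhomology-mediated: >=4-nt annealing between one overhang
              and sequence adjacent to the other end, with deletion
    Type III  direct ligation without gap-filling: terminal nucleotide(s)
              removed, >=3-nt pairing tolerating one mismatch (resolved
              later by mismatch repair)
    Type IV   end-bridging: one overhang degraded to a blunt end that
              primes synthesis across the other, intact, overhang

Non-complementary 3' overhangs
    Type I    gap-filling on both strands across intact overhangs
    Type II   microhomology-mediated annealing plus gap-filling on exactly
              one strand
    Type III  microhomology-mediated annealing with no gap-filling

Reconstruction model (top strand, left-to-right): a candidate removes
``trim_left_prot`` bases from the left end's top strand 3' terminus,
``trim_right_rec`` bases from the right end's recessed top strand 5'
terminus, and places ``insertion_top`` net-new bases between the remnants:

    junction == left_top[:len-trim_left] + insertion + right_top[trim_right:]

Net-new bases opposite a retained bottom-strand overhang are recognised as
templated fill; within an annealed pairing region one structural mismatch
is tolerated, and the junction may carry either post-mismatch-repair allele
at that position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .assay import AssayConfig, AssayError, Junction, MalformedInputError, revcomp

__all__ = [
    "RepairType",
    "REPAIR_TYPES",
    "repair_type",
    "type_labels",
    "Explanation",
    "ClassifiedJunction",
    "TypeDistribution",
    "enumerate_explanations",
    "rank_explanations",
    "classify",
    "classify_junction",
    "classify_cohort",
]

_COMP = str.maketrans("ACGT", "TGCA")


def _comp(base: str) -> str:
    return base.translate(_COMP)


@dataclass(frozen=True)
class RepairType:
    """A mechanistic repair class within one assay system."""

    system: str   # 'partial' or 'noncomp'
    label: str    # 'I', 'II', 'III', 'IV' (IV only in the partial system)
    description: str

    def __str__(self) -> str:
        return f"{self.system}:{self.label}"


REPAIR_TYPES: dict[tuple[str, str], RepairType] = {
    ("partial", "I"): RepairType("partial", "I", "Gap-filling-mediated"),
    ("partial", "II"): RepairType("partial", "II", "MH-mediated"),
    ("partial", "III"): RepairType("partial", "III", "Direct ligation with no gap-filling"),
    ("partial", "IV"): RepairType("partial", "IV", "End-bridging"),
    ("noncomp", "I"): RepairType("noncomp", "I", "Gap-filling (2-strands)"),
    ("noncomp", "II"): RepairType("noncomp", "II", "MH-mediated and Gap-filling (1-strand)"),
    ("noncomp", "III"): RepairType("noncomp", "III", "MH-mediated no Gap-filling"),
}


def repair_type(system: str, label: str) -> RepairType:
    try:
        return REPAIR_TYPES[(system, label)]
    except KeyError:
        raise AssayError(f"no repair type {label!r} in the {system!r} system") from None


def type_labels(system: str) -> list[str]:
    """Ordered labels of the taxonomy for one assay system."""
    labels = [t.label for (s, _), t in REPAIR_TYPES.items() if s == system]
    if not labels:
        raise AssayError(f"unknown assay system {system!r}")
    return labels


@dataclass(frozen=True)
class Explanation:
    """One repair event that reconstructs an observed junction exactly.

    Trims are in nucleotides.  ``trim_left_prot`` counts removal from the
    left end's protruding top strand (values above the overhang length eat
    into flanking duplex); ``trim_right_rec`` counts removal from the right
    end's recessed top strand; ``trim_right_prot`` is the inferred loss
    from the right end's protruding bottom overhang and ``trim_left_rec``
    the implied loss of left bottom strand under a beyond-overhang
    deletion.  ``mh_len`` is the longest run of junction bases attributable
    to both parents, whether by direct sequence identity at the breakpoint
    or by base pairing between retained overhang bases.  ``mm_pos`` (when
    not None) is the junction coordinate of a tolerated pairing mismatch
    whose letter follows the bottom-strand (right-end) allele.
    """

    assay_name: str
    trim_left_prot: int
    trim_right_rec: int
    insertion_top: str
    mm_pos: int | None = None
    # annotations (derived; filled by the enumerator)
    mh_len: int = 0
    pairing_len: int = 0
    mismatches_in_pairing: int = 0
    templated_top: bool = False
    templated_bottom: bool = False
    trim_right_prot: int = 0
    trim_left_rec: int = 0
    bottom_fill_len: int = 0

    @property
    def total_trimmed(self) -> int:
        return self.trim_left_prot + self.trim_right_rec

    @property
    def cost(self) -> int:
        """Parsimony cost: trimmed plus inserted top-strand nucleotides."""
        return self.total_trimmed + len(self.insertion_top)

    def reconstruct(self, assay: AssayConfig) -> str:
        """Rebuild the junction top strand this explanation describes."""
        lt, rt = assay.left_top, assay.right_top
        u = lt[: len(lt) - self.trim_left_prot]
        if self.mm_pos is not None:
            allele = _comp(assay.right_end.overhang[len(u) - 1 - self.mm_pos])
            u = u[: self.mm_pos] + allele + u[self.mm_pos + 1:]
        return u + self.insertion_top + rt[self.trim_right_rec:]


@dataclass(frozen=True)
class ClassifiedJunction:
    """Classification outcome for one junction."""

    junction_id: str
    explanation: Explanation | None
    repair_type: RepairType | None
    alternates: int = 0
    ambiguous: bool = False
    unclassifiable: bool = False


@dataclass
class TypeDistribution:
    """Per-type counts over a cohort of classified junctions.

    Percentages are always rendered from counts (nearest integer), never
    the reverse; unclassifiable and ambiguous junctions are tallied
    separately and excluded from ``n`` and the percentages.
    """

    system: str
    counts: dict[str, int]
    unclassifiable: int = 0
    ambiguous: int = 0

    def __post_init__(self):
        labels = type_labels(self.system)
        unknown = set(self.counts) - set(labels)
        if unknown:
            raise AssayError(f"labels {sorted(unknown)} not in the {self.system} taxonomy")
        self.counts = {lab: int(self.counts.get(lab, 0)) for lab in labels}

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def percentages(self) -> dict[str, int | None]:
        """Nearest-integer percentages, or None-marked when the cohort is empty."""
        if self.n == 0:
            return {lab: None for lab in self.counts}
        # round half away from zero, matching printed-table convention
        return {
            lab: int(100.0 * c / self.n + 0.5) for lab, c in self.counts.items()
        }

    def as_vector(self) -> list[int]:
        return [self.counts[lab] for lab in type_labels(self.system)]


def _max_shared_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _annotate(
    assay: AssayConfig,
    t1: int,
    t2: int,
    ins: str,
    mm_pos: int | None,
    junction_top: str,
) -> Explanation:
    """Attach mechanistic annotations to a raw (trim, trim, insertion) event."""
    lt, rt = assay.left_top, assay.right_top
    R = assay.right_end.overhang          # bottom strand, 5'->3'
    V = assay.right_end.virtual_top       # top-strand image, left-to-right
    n_ov = assay.overhang_length
    u_len = len(lt) - t1
    g = len(ins)
    p = u_len + g                          # junction coordinate where right top begins

    # --- breakpoint-shift microhomology (direct sequence identity) ---
    m1 = m2 = 0
    if g == 0:
        # right-shift: bases past the breakpoint also present in the left parent
        lim = min(t1, len(rt) - t2)
        while m1 < lim and lt[u_len + m1] == rt[t2 + m1]:
            m1 += 1
        # left-shift: bases before the breakpoint also present in the right parent
        lim = min(t2, u_len)
        while m2 < lim and junction_top[p - 1 - m2] == rt[t2 - 1 - m2]:
            m2 += 1
    string_mh = m1 + m2

    # --- pairing between the left remnant and the retained right overhang ---
    # Only geometrically possible while the right end's top strand is intact
    # (t2 == 0): overhang base R[g+m] lies opposite left remnant position
    # u[-1-m]; one structural mismatch inside the run is tolerated.
    pairing = 0
    mismatches = 0
    if t2 == 0:
        run = 0
        mm = 0
        last_was_mm = False
        while g + run < n_ov and u_len - 1 - run >= 0:
            structural = lt[u_len - 1 - run] == _comp(R[g + run])
            if not structural:
                if mm == 1:      # a second mismatch ends the annealed run
                    break
                mm = 1
                last_was_mm = True
            else:
                last_was_mm = False
            run += 1
        if last_was_mm:       # a dangling terminal mismatch is not a pair
            run -= 1
            mm -= 1
        pairing = run
        mismatches = mm

    templated_top = bool(g) and t2 == 0 and g <= n_ov and ins == V[n_ov - g:]

    retained_l = max(0, n_ov - t1)
    covered_l = min(max(pairing, m2), retained_l)
    bottom_fill = retained_l - covered_l

    if t2 > 0:
        trim_right_prot = n_ov
    elif templated_top:
        trim_right_prot = max(0, n_ov - (g + pairing))
    elif g > 0:
        trim_right_prot = n_ov
    else:
        trim_right_prot = n_ov - pairing

    return Explanation(
        assay_name=assay.name,
        trim_left_prot=t1,
        trim_right_rec=t2,
        insertion_top=ins,
        mm_pos=mm_pos,
        mh_len=max(string_mh, pairing),
        pairing_len=pairing,
        mismatches_in_pairing=mismatches,
        templated_top=templated_top,
        templated_bottom=bottom_fill > 0,
        trim_right_prot=trim_right_prot,
        trim_left_rec=max(0, t1 - n_ov),
        bottom_fill_len=bottom_fill,
    )


def enumerate_explanations(junction: Junction) -> list[Explanation]:
    """All repair events within the assay bounds that rebuild the junction.

    Candidates satisfy the reconstruction identity exactly, except that one
    mismatch inside an annealed pairing region may resolve to the
    right-end (bottom-strand) allele, in which case the junction letter at
    that position matches the complement of the paired overhang base
    rather than the left parent.  An empty result simply means the
    junction is unexplainable within bounds (the caller marks it
    unclassifiable).
    """
    assay = junction.assay
    J = junction.top
    lt, rt = assay.left_top, assay.right_top
    R = assay.right_end.overhang
    n_ov = assay.overhang_length
    max_t1 = min(assay.max_deletion, len(lt) - len(assay.left_anchor))
    max_t2 = min(assay.max_deletion, len(rt) - len(assay.right_anchor))
    out: list[Explanation] = []

    for t1 in range(0, max_t1 + 1):
        u = lt[: len(lt) - t1]
        if not J.startswith(u):
            continue
        for t2 in range(0, max_t2 + 1):
            mid_len = len(J) - len(u) - (len(rt) - t2)
            if mid_len < 0 or mid_len > assay.max_insertion:
                continue
            if not J.endswith(rt[t2:]):
                continue
            ins = J[len(u): len(u) + mid_len]
            out.append(_annotate(assay, t1, t2, ins, None, J))

    # Mismatch-tolerant candidates: no insertion, right top intact, exactly
    # one disagreement with the left parent inside the pairing window whose
    # junction letter equals the bottom-strand allele.
    u_len = len(J) - len(rt)
    t1 = len(lt) - u_len
    if 0 <= t1 <= max_t1 and J.endswith(rt) and u_len > 0:
        u0 = lt[:u_len]
        diffs = [j for j in range(u_len) if J[j] != u0[j]]
        if len(diffs) == 1:
            j = diffs[0]
            e = u_len - 1 - j          # distance from the remnant 3' terminus
            if e < n_ov and J[j] == _comp(R[e]):
                cand = _annotate(assay, t1, 0, "", j, J)
                # the tolerated mismatch must lie inside the pairing run
                if e < cand.pairing_len:
                    out.append(cand)
    return out


def _rank_key(e: Explanation):
    # untemplated insertions sort after templated ones; explanations with no
    # insertion are neutral on that criterion
    ins_penalty = 1 if (e.insertion_top and not e.templated_top) else 0
    return (
        e.cost,
        -e.mh_len,
        e.mismatches_in_pairing,
        ins_penalty,
        e.trim_left_prot,        # left-aligned canonical placement
        e.trim_right_rec,
        e.insertion_top,
        -1 if e.mm_pos is None else e.mm_pos,
    )


def rank_explanations(candidates: Sequence[Explanation]) -> Explanation:
    """The unique winner under the parsimony total order.

    Minimise (trimmed + inserted nucleotides); then maximise microhomology;
    then minimise pairing mismatches; then prefer templated insertions;
    then left-align junction-ambiguous bases.  The final lexicographic
    components make the order total, so the result is deterministic.
    """
    if not candidates:
        raise MalformedInputError("rank_explanations requires a non-empty candidate list")
    return min(candidates, key=_rank_key)


def _classify_features(e: Explanation, n_ov: int):
    g = len(e.insertion_top)
    full_right_retention = e.trim_right_prot == 0
    return g, full_right_retention


def classify(explanation: Explanation, assay: AssayConfig) -> RepairType | None:
    """Assign a repair type, or None when no clause of the system fits.

    Partial system precedence I > III > IV > II; non-complementary system
    I > II > III.  Precedence matters only for explanations satisfying
    several clauses and prefers readings that preserve more end structure.
    """
    if explanation.assay_name != assay.name:
        raise AssayError(
            f"explanation was built for assay {explanation.assay_name!r}, "
            f"not {assay.name!r}"
        )
    n_ov = assay.overhang_length
    t1, t2 = explanation.trim_left_prot, explanation.trim_right_rec
    g = len(explanation.insertion_top)
    r = explanation.pairing_len
    mm = explanation.mismatches_in_pairing
    fill_bottom = explanation.bottom_fill_len

    if assay.system == "partial":
        if (t1 == 0 and t2 == 0 and g > 0 and explanation.templated_top
                and g + r == n_ov and mm == 0):
            return repair_type("partial", "I")
        if (t1 <= 1 and t2 == 0 and g == 0 and r >= n_ov - 1 and mm <= 1
                and fill_bottom == 0 and explanation.trim_right_prot <= 1):
            return repair_type("partial", "III")
        if t2 == 0 and (
            # right end blunted: bottom synthesis across the intact left overhang
            (t1 == 0 and g == 0 and fill_bottom > 0)
            # left end blunted/trimmed: top synthesis templated across the
            # fully retained right overhang
            or (t1 >= 1 and g > 0 and explanation.templated_top
                and explanation.trim_right_prot == 0
                and explanation.mismatches_in_pairing == 0)
        ):
            return repair_type("partial", "IV")
        if g == 0 and explanation.mh_len >= n_ov and (t1 > n_ov or t2 > 0):
            return repair_type("partial", "II")
        return None

    # non-complementary taxonomy
    if (t1 == 0 and t2 == 0 and g > 0 and explanation.templated_top
            and g + r == n_ov and fill_bottom > 0):
        return repair_type("noncomp", "I")
    if explanation.mh_len >= 1 and (
        (g == 0 and fill_bottom > 0)
        or (g > 0 and explanation.templated_top and fill_bottom == 0)
    ):
        return repair_type("noncomp", "II")
    if g == 0 and fill_bottom == 0 and explanation.mh_len >= 1:
        return repair_type("noncomp", "III")
    return None


def classify_junction(junction: Junction) -> ClassifiedJunction:
    """Enumerate, rank and classify a single junction."""
    candidates = enumerate_explanations(junction)
    if not candidates:
        return ClassifiedJunction(
            junction_id=junction.id, explanation=None, repair_type=None,
            unclassifiable=True,
        )
    winner = rank_explanations(candidates)
    wkey = _rank_key(winner)[:4]
    co_optimal = [c for c in candidates if _rank_key(c)[:4] == wkey]
    rtype = classify(winner, junction.assay)
    co_types = {classify(c, junction.assay) for c in co_optimal}
    ambiguous = len(co_types - {None}) > 1
    return ClassifiedJunction(
        junction_id=junction.id,
        explanation=winner,
        repair_type=rtype,
        alternates=len(co_optimal),
        ambiguous=ambiguous,
        unclassifiable=rtype is None,
    )


def classify_cohort(junctions: Iterable[Junction]) -> TypeDistribution:
    """Classify a cohort sharing one assay into a per-type distribution."""
    junctions = list(junctions)
    if not junctions:
        raise MalformedInputError(
            "classify_cohort needs at least one junction to infer the assay; "
            "build an empty TypeDistribution directly instead"
        )
    first = junctions[0].assay
    if any(j.assay != first for j in junctions[1:]):
        names = sorted({j.assay.name for j in junctions})
        raise AssayError(f"cohort mixes assays: {names}")
    system = junctions[0].assay.system
    counts = {lab: 0 for lab in type_labels(system)}
    unclassifiable = ambiguous = 0
    for j in junctions:
        cj = classify_junction(j)
        if cj.unclassifiable:
            unclassifiable += 1
        elif cj.ambiguous:
            ambiguous += 1
        else:
            counts[cj.repair_type.label] += 1
    return TypeDistribution(
        system=system, counts=counts,
        unclassifiable=unclassifiable, ambiguous=ambiguous,
    )
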