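"""Synthetic junction, cohort and plating-experiment simulator.

The simulator executes each repair mechanism literally on the configured
DSB ends — anneal at the type-specific register, trim, fill templated gaps,
ligate — so every emitted junction is a mechanistically valid sequence with
a known ground-truth repair type and explanation.  Cohorts mix types
according to a per-strain probability profile; the shipped defaults are
the empirical per-genotype mixtures (counts / n) of the translocation
study this package models.

Randomness: every sampling call derives from a single integer seed.  Each
junction index ``i`` draws from its own substream
(``SeedSequence(entropy=seed, spawn_key=(i,))``), so cohorts are
reproducible regardless of iteration order, and junction ``i`` of a cohort
is identical however many junctions follow it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .assay import AssayConfig, ConfigError, Junction, revcomp
from .explain import Explanation, RepairType, repair_type, type_labels
from .stats import PlatingExperiment

__all__ = [
    "StrainProfile",
    "SimulatedJunction",
    "simulate_junction",
    "simulate_cohort",
    "simulate_plating",
    "default_profile",
    "default_strains",
    "PARTIAL_TYPE_COUNTS",
    "NONCOMP_TYPE_COUNTS",
]

# Published per-genotype repair-type counts (partially-complementary assay:
# Types I-IV; non-complementary assay: Types I-III).  Rows with no
# recovered translocants are omitted.
PARTIAL_TYPE_COUNTS: dict[str, list[int]] = {
    "WT": [16, 5, 2, 1],
    "pol4Δ": [0, 12, 8, 1],
    "pol4Δ [POL4]": [24, 2, 9, 0],
    "pol4Δ [pol4-D367A,D369A]": [0, 3, 12, 2],
    "pol4Δ [pol4ΔBRCT]": [0, 7, 9, 2],
    "pol4Δ [pol4-T64A]": [26, 0, 5, 4],
    "pol4Δ [pol4-T540A]": [13, 6, 10, 7],
    "tel1Δ": [9, 6, 4, 8],
    "tel1Δ pol4Δ": [6, 4, 10, 3],
    "tel1Δ pol4Δ [POL4]": [13, 7, 7, 3],
    "tel1Δ pol4Δ [pol4-T540A]": [8, 6, 11, 5],
}

NONCOMP_TYPE_COUNTS: dict[str, list[int]] = {
    "WT": [7, 18, 0],
    "pol4Δ": [0, 7, 13],
    "pol4Δ [POL4]": [15, 11, 5],
    "pol4Δ [pol4-T64A]": [15, 11, 1],
    "pol4Δ [pol4-T540A]": [6, 12, 19],
}


@dataclass(frozen=True)
class StrainProfile:
    """Type mixture and mechanism parameters for one simulated genotype.

    ``type_probs`` maps repair-type labels to sampling probabilities (must
    sum to 1).  ``mh_site_range`` bounds, per type label, the total
    deletion of microhomology-mediated placements the simulator may choose
    (inclusive, in nucleotides of top-strand loss).  ``mmr_resolution_prob``
    is the probability that a tolerated pairing mismatch resolves to the
    left-end allele.
    """

    name: str
    system: str
    type_probs: dict[str, float]
    mh_site_range: dict[str, tuple[int, int]] = field(default_factory=dict)
    mmr_resolution_prob: float = 0.5

    def __post_init__(self):
        labels = type_labels(self.system)
        unknown = set(self.type_probs) - set(labels)
        if unknown:
            raise ConfigError(f"type_probs has labels {sorted(unknown)} "
                              f"outside the {self.system} taxonomy")
        total = sum(self.type_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"type probabilities sum to {total}, expected 1")
        if any(p < 0 for p in self.type_probs.values()):
            raise ConfigError("type probabilities must be non-negative")
        if not (0.0 <= self.mmr_resolution_prob <= 1.0):
            raise ConfigError("mmr_resolution_prob must lie in [0, 1]")

    def prob_vector(self) -> tuple[list[str], list[float]]:
        labels = type_labels(self.system)
        return labels, [float(self.type_probs.get(lab, 0.0)) for lab in labels]


@dataclass(frozen=True)
class SimulatedJunction:
    """A simulated junction with its ground truth."""

    junction: Junction
    truth: RepairType
    truth_explanation: Explanation

    def __post_init__(self):
        rebuilt = self.truth_explanation.reconstruct(self.junction.assay)
        if rebuilt != self.junction.top:
            raise AssertionError(
                f"simulator self-check failed for {self.junction.id}: "
                f"truth explanation does not reconstruct the emitted sequence"
            )


def default_profile(system: str, strain: str = "WT", **overrides) -> StrainProfile:
    """Profile with type probabilities = published counts / n for a strain."""
    table = PARTIAL_TYPE_COUNTS if system == "partial" else NONCOMP_TYPE_COUNTS
    if strain not in table:
        raise ConfigError(
            f"no default profile for strain {strain!r} in the {system} system; "
            f"known strains: {sorted(table)}"
        )
    counts = table[strain]
    labels = type_labels(system)
    n = sum(counts)
    probs = {lab: c / n for lab, c in zip(labels, counts)}
    kwargs = dict(name=strain, system=system, type_probs=probs)
    kwargs.update(overrides)
    return StrainProfile(**kwargs)


def default_strains(system: str) -> list[str]:
    table = PARTIAL_TYPE_COUNTS if system == "partial" else NONCOMP_TYPE_COUNTS
    return list(table)


# ---------------------------------------------------------------------------
# mechanism site enumeration


def _fill_registers(assay: AssayConfig) -> list[int]:
    """Perfect terminal pairing registers that leave a gap to fill."""
    return [k for k in assay.pairing_registers if k < assay.overhang_length]


def _mh_sites_right(assay: AssayConfig, min_m: int, lo: int, hi: int) -> list[tuple[int, int]]:
    """(m, t2) placements annealing the left overhang's 3' suffix of length
    m to right-flank sequence, deleting t2 right-top nucleotides."""
    L, rt = assay.left_end.overhang, assay.right_top
    n_ov = assay.overhang_length
    sites = []
    for m in range(min_m, n_ov + 1):
        suffix = L[n_ov - m:]
        for d in range(0, len(rt) - m + 1):
            t2 = d + m
            if t2 > min(hi, assay.max_deletion):
                continue
            if t2 < lo:
                continue
            if rt[d: d + m] == suffix:
                sites.append((m, t2))
    return sites


def _mh_sites_left(assay: AssayConfig, min_m: int, lo: int, hi: int) -> list[tuple[int, int]]:
    """(m, t1) placements annealing the right overhang's 3'-terminal m bases
    to left-flank sequence, deleting t1 left-top nucleotides (beyond the
    overhang)."""
    R, lt = assay.right_end.overhang, assay.left_top
    n_ov = assay.overhang_length
    sites = []
    for m in range(min_m, n_ov + 1):
        probe = revcomp(R[:m])   # top-strand image of the paired window
        for q in range(m, len(lt) + 1):
            t1 = len(lt) - q
            if t1 <= n_ov:       # must delete beyond the left overhang
                continue
            if t1 > min(hi, assay.max_deletion) or t1 < lo:
                continue
            if lt[q - m: q] == probe:
                sites.append((m, t1))
    return sites


def _build(assay, t1, t2, ins, mm_pos=None):
    """Annotated truth explanation for a generated event."""
    from .explain import _annotate  # shared annotation logic

    lt, rt = assay.left_top, assay.right_top
    u = lt[: len(lt) - t1]
    if mm_pos is not None:
        allele = revcomp(assay.right_end.overhang[len(u) - 1 - mm_pos])
        u = u[:mm_pos] + allele + u[mm_pos + 1:]
    seq = u + ins + rt[t2:]
    return seq, _annotate(assay, t1, t2, ins, mm_pos, seq)


def _simulate_partial(label, assay, profile, rng):
    n_ov = assay.overhang_length
    R = assay.right_end.overhang
    V = assay.right_end.virtual_top
    if label == "I":
        registers = _fill_registers(assay)
        if not registers:
            raise ConfigError("assay has no gap-leaving pairing register for Type I")
        k = registers[rng.integers(len(registers))]
        ins = V[n_ov - (n_ov - k):]  # fill opposite the unpaired overhang bases
        return _build(assay, 0, 0, ins)
    if label == "II":
        lo, hi = profile.mh_site_range.get("II", (1, assay.max_deletion))
        sites = [("right", m, t) for m, t in _mh_sites_right(assay, n_ov, lo, hi)]
        sites += [("left", m, t) for m, t in _mh_sites_left(assay, n_ov, lo, hi)]
        if not sites:
            raise ConfigError(
                "no >=4-nt microhomology placement exists between an overhang "
                "and the opposing flank within max_deletion; cannot simulate "
                "Type II for this assay"
            )
        side, m, t = sites[rng.integers(len(sites))]
        if side == "right":
            return _build(assay, 0, t, "")
        return _build(assay, t, 0, "")
    if label == "III":
        # trim one terminal nucleotide from each protruding strand, anneal
        # the remnants; the structural mismatch resolves by MMR
        lt = assay.left_top
        u_len = len(lt) - 1
        mism = [m for m in range(n_ov - 1)
                if lt[u_len - 1 - m] != revcomp(R[m])]
        if len(mism) > 1:
            raise ConfigError("Type III pairing would need >1 mismatch in this assay")
        mm_pos = None
        if mism and rng.random() >= profile.mmr_resolution_prob:
            mm_pos = u_len - 1 - mism[0]
        return _build(assay, 1, 0, "", mm_pos)
    if label == "IV":
        if rng.random() < 0.5:
            return _build(assay, 0, 0, "")           # right end blunted
        return _build(assay, n_ov, 0, V)             # left end blunted
    raise ConfigError(f"type {label!r} is not valid for the partial system")


def _simulate_noncomp(label, assay, profile, rng):
    n_ov = assay.overhang_length
    V = assay.right_end.virtual_top
    if label == "I":
        return _build(assay, 0, 0, V)
    if label == "II":
        lo, hi = profile.mh_site_range.get("II", (1, 12))
        sites = _mh_sites_right(assay, 2, lo, hi)
        if not sites:
            raise ConfigError(
                "no suffix microhomology of the left overhang exists in the "
                "right flank within range; cannot simulate Type II"
            )
        m, t2 = sites[rng.integers(len(sites))]
        return _build(assay, 0, t2, "")
    if label == "III":
        lo, hi = profile.mh_site_range.get("III", (n_ov + 1, assay.max_deletion))
        sites = _mh_sites_left(assay, n_ov, lo, hi)
        if not sites:
            raise ConfigError(
                "no full-overhang annealing site exists in the left flank "
                "within range; cannot simulate Type III"
            )
        m, t1 = sites[rng.integers(len(sites))]
        return _build(assay, t1, 0, "")
    raise ConfigError(f"type {label!r} is not valid for the non-complementary system")


def simulate_junction(
    rtype: RepairType | str,
    assay: AssayConfig,
    profile: StrainProfile | None = None,
    seed: int | np.random.Generator = 0,
    junction_id: str = "sim",
) -> SimulatedJunction:
    """Generate one junction by executing a repair mechanism literally."""
    if profile is None:
        profile = default_profile(assay.system)
    label = rtype.label if isinstance(rtype, RepairType) else str(rtype)
    truth = repair_type(assay.system, label)  # validates type/assay match
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if assay.system == "partial":
        seq, expl = _simulate_partial(label, assay, profile, rng)
    else:
        seq, expl = _simulate_noncomp(label, assay, profile, rng)
    junction = Junction(id=junction_id, top=seq, assay=assay)
    return SimulatedJunction(junction=junction, truth=truth, truth_explanation=expl)


def simulate_cohort(
    profile: StrainProfile,
    n: int,
    assay: AssayConfig,
    seed: int = 0,
) -> list[SimulatedJunction]:
    """n junctions with types drawn i.i.d. from the profile's mixture."""
    if n < 0:
        raise ConfigError("cohort size must be non-negative")
    if profile.system != assay.system:
        raise ConfigError(
            f"profile is for the {profile.system!r} system, assay is "
            f"{assay.system!r}"
        )
    labels, probs = profile.prob_vector()
    # FASTA ids must be whitespace-free; strain names may not be
    stem = re.sub(r"[^\w.-]+", "_", profile.name)
    out = []
    for i in range(n):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(i,))
        )
        label = labels[rng.choice(len(labels), p=probs)]
        out.append(
            simulate_junction(label, assay, profile, rng,
                              junction_id=f"{stem}-{i + 1:03d}")
        )
    return out


def simulate_plating(
    true_freq: float,
    n_cells: int,
    seed: int | np.random.Generator = 0,
    true_survival: float = 0.3,
) -> PlatingExperiment:
    """Binomial colony counts for one plating experiment.

    ``n_cells`` cells are plated (pre-induction SC count); survivors on
    galactose arise with probability ``true_survival`` and Leu+
    translocants with probability ``true_freq``.  The frequency estimator
    applied to these counts is unbiased for ``true_freq``.
    """
    if not (0.0 <= true_freq <= 1.0):
        raise ConfigError("true_freq must lie in [0, 1]")
    if n_cells < 0:
        raise ConfigError("n_cells must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_cells = int(n_cells)
    return PlatingExperiment(
        colonies_sc=n_cells,
        colonies_sgal=int(rng.binomial(n_cells, true_survival)),
        colonies_sgal_leu=int(rng.binomial(n_cells, true_freq)),
    )
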