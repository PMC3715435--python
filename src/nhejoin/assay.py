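"""DSB end and translocation-assay models.

The assays represented here induce two site-specific double-strand breaks
(DSBs) on different chromosomes with staggered endonuclease cuts (HO and
I-SceI), each leaving a 4-nt 3'-protruding single-stranded overhang.
Nonhomologous end-joining (NHEJ) of the two ends in trans reconstitutes a
selectable marker whose intron spans the new junction, so every recovered
translocant yields one sequenced junction.

Geometry conventions used throughout:

* All sequences are written on the top strand, 5'->3' left-to-right; the
  bottom strand is the reverse complement.
* The *left* end contributes the upstream side of the junction.  Its
  protruding 3' overhang is on the top strand, so its full top strand is
  ``duplex_top + overhang``.
* The *right* end contributes the downstream side.  Its protruding 3'
  overhang is on the bottom strand (written 5'->3' on that strand), so its
  top strand is recessed and equals ``duplex_top`` alone.  Spatially the
  overhang occupies the four positions immediately left of ``duplex_top``;
  its base-paired top-strand image there would read
  ``reverse_complement(overhang)``.
* Coordinates are 0-based, half-open; cuts fall between bases.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field, replace
from importlib import resources

__all__ = [
    "AssayError",
    "AmbiguousCutError",
    "UnsupportedOverhangError",
    "ConfigError",
    "MalformedInputError",
    "revcomp",
    "validate_bases",
    "CutSiteSpec",
    "DsbEnd",
    "AssayConfig",
    "Junction",
    "apply_cut",
    "religate",
    "load_assay",
    "builtin_assay",
    "BUILTIN_ASSAYS",
    "ISCEI",
    "HO",
]

_COMP = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")


class AssayError(ValueError):
    """Base class for assay-model contract violations."""


class AmbiguousCutError(AssayError):
    """Recognition sequence absent or present more than once."""


class UnsupportedOverhangError(AssayError):
    """Cut offsets do not describe a positive-length 3' overhang."""


class ConfigError(AssayError):
    """Invalid or inconsistent assay configuration."""


class MalformedInputError(AssayError):
    """Junction or sequence input that fails validation."""


def revcomp(seq: str) -> str:
    """Reverse complement of a top-strand sequence."""
    return seq.translate(_COMP)[::-1]


def validate_bases(seq: str, what: str = "sequence", allow_empty: bool = False) -> str:
    """Uppercase and validate a DNA string over the strict ACGT alphabet."""
    if not isinstance(seq, str):
        raise MalformedInputError(f"{what} must be a string, got {type(seq).__name__}")
    s = seq.strip().upper()
    if not s and not allow_empty:
        raise MalformedInputError(f"{what} must be non-empty")
    bad = set(s) - _ALPHABET
    if bad:
        raise MalformedInputError(
            f"{what} contains characters outside ACGT: {sorted(bad)}"
        )
    return s


@dataclass(frozen=True)
class CutSiteSpec:
    """A staggered endonuclease cut within its recognition sequence.

    ``top_cut`` and ``bottom_cut`` are 0-based offsets into ``recognition``;
    a cut at offset ``i`` falls between positions ``i-1`` and ``i``.
    ``top_cut`` locates the scission that creates the two recessed termini
    and ``bottom_cut`` the scission that creates the protruding 3' termini,
    so ``bottom_cut - top_cut`` equals the 3'-overhang length and must be
    positive.  Cutting a duplex leaves a left end whose top strand runs to
    ``bottom_cut`` (last ``overhang_length`` bases single-stranded) and a
    right end whose bottom strand protrudes by the reverse complement of
    the same window.
    """

    name: str
    recognition: str
    top_cut: int
    bottom_cut: int

    def __post_init__(self):
        object.__setattr__(self, "recognition", validate_bases(self.recognition, "recognition"))
        if not (0 <= self.top_cut <= len(self.recognition)):
            raise ConfigError(f"top_cut {self.top_cut} outside recognition sequence")
        if not (0 <= self.bottom_cut <= len(self.recognition)):
            raise ConfigError(f"bottom_cut {self.bottom_cut} outside recognition sequence")
        if self.bottom_cut <= self.top_cut:
            raise UnsupportedOverhangError(
                f"{self.name}: bottom_cut ({self.bottom_cut}) must exceed top_cut "
                f"({self.top_cut}); blunt or 5'-overhang cuts are not supported"
            )

    @property
    def overhang_length(self) -> int:
        return self.bottom_cut - self.top_cut


@dataclass(frozen=True)
class DsbEnd:
    """One broken chromosome end entering a junction.

    ``side`` is the end's position relative to the junction being formed.
    ``duplex_top`` is the top strand of the retained double-stranded
    context; ``overhang`` is the 4-nt single-stranded 3' extension written
    5'->3' on its own strand (top strand for a left end, bottom strand for
    a right end, which is forced by the geometry of two 3'-protruding ends
    facing each other).
    """

    side: str
    duplex_top: str
    overhang: str
    overhang_strand: str

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ConfigError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.overhang_strand not in ("top", "bottom"):
            raise ConfigError(f"overhang_strand must be 'top' or 'bottom'")
        expected = "top" if self.side == "left" else "bottom"
        if self.overhang_strand != expected:
            raise ConfigError(
                f"a {self.side} end joined with a 3' overhang must carry its "
                f"overhang on the {expected} strand, got {self.overhang_strand!r}"
            )
        object.__setattr__(self, "duplex_top", validate_bases(self.duplex_top, "duplex_top"))
        object.__setattr__(self, "overhang", validate_bases(self.overhang, "overhang"))

    @property
    def top_strand(self) -> str:
        """Full top strand of the end (duplex plus any top-strand overhang)."""
        if self.side == "left":
            return self.duplex_top + self.overhang
        return self.duplex_top

    @property
    def virtual_top(self) -> str:
        """Top-strand image of the bottom overhang (right ends only).

        These bases exist only on the bottom strand of the end; they appear
        in a repaired top strand only as newly synthesised, overhang-templated
        fill.
        """
        if self.side != "right":
            raise AssayError("virtual_top is defined for right ends only")
        return revcomp(self.overhang)


def _perfect_terminal_registers(left_overhang: str, right_overhang: str) -> list[int]:
    """Annealing registers where the two 3' termini pair perfectly.

    Register ``k`` overlaps the ``k`` 3'-terminal bases of each overhang;
    it is valid when every one of the ``k`` opposed base pairs is
    Watson-Crick complementary.  Returns all valid ``k >= 1``.
    """
    L, R = left_overhang, right_overhang
    n = min(len(L), len(R))
    comp = str.maketrans("ACGT", "TGCA")
    registers = []
    for k in range(1, n + 1):
        if all(L[len(L) - k + m] == R[len(R) - 1 - m].translate(comp) for m in range(k)):
            registers.append(k)
    return registers


@dataclass(frozen=True)
class AssayConfig:
    """A two-ended translocation (or in-cis deletion) junction assay.

    ``max_deletion`` bounds the nucleotides that may be trimmed from either
    end's top strand (overhang included) and ``max_insertion`` the net-new
    top-strand bases at the junction; both reflect the selection constraint
    that the intron spanning the junction must remain functional, and the
    observation that microhomology use in recovered events never exceeds a
    few nucleotides.
    """

    name: str
    left_end: DsbEnd
    right_end: DsbEnd
    left_anchor: str
    right_anchor: str
    max_deletion: int = 25
    max_insertion: int = 6
    karyotype: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.name not in ("partial", "noncomp", "cis"):
            raise ConfigError(f"assay name must be partial/noncomp/cis, got {self.name!r}")
        if self.left_end.side != "left" or self.right_end.side != "right":
            raise ConfigError("left_end/right_end sides are inconsistent")
        if len(self.left_end.overhang) != len(self.right_end.overhang):
            raise ConfigError("left and right overhang lengths differ")
        object.__setattr__(self, "left_anchor", validate_bases(self.left_anchor, "left_anchor"))
        object.__setattr__(self, "right_anchor", validate_bases(self.right_anchor, "right_anchor"))
        if not self.left_end.duplex_top.startswith(self.left_anchor):
            raise ConfigError("left_anchor is not a prefix of the left end context")
        if not self.right_end.duplex_top.endswith(self.right_anchor):
            raise ConfigError("right_anchor is not a suffix of the right end context")
        if self.max_deletion <= 0 or self.max_insertion <= 0:
            raise ConfigError("max_deletion and max_insertion must be positive")
        registers = self.pairing_registers
        if self.name == "partial" and not registers:
            raise ConfigError(
                "assay declared 'partial' but the overhangs share no perfect "
                "terminal pairing register"
            )
        if self.name in ("noncomp", "cis") and registers:
            raise ConfigError(
                f"assay declared '{self.name}' but the overhangs pair perfectly "
                f"at register(s) {registers}; ends are not non-complementary"
            )

    @property
    def overhang_length(self) -> int:
        return len(self.left_end.overhang)

    @property
    def left_top(self) -> str:
        """Full top strand of the left end (flank + 3' overhang)."""
        return self.left_end.top_strand

    @property
    def right_top(self) -> str:
        """Top strand of the right end (recessed; excludes the bottom overhang)."""
        return self.right_end.top_strand

    @property
    def pairing_registers(self) -> list[int]:
        """Registers (overlap lengths) with perfect terminal overhang pairing."""
        return _perfect_terminal_registers(self.left_end.overhang, self.right_end.overhang)

    @property
    def complementarity(self) -> str:
        """'partial' if any perfect terminal register exists, else 'none'."""
        return "partial" if self.pairing_registers else "none"

    @property
    def system(self) -> str:
        """Repair-type taxonomy this assay is scored against."""
        return "partial" if self.name == "partial" else "noncomp"


@dataclass(frozen=True)
class Junction:
    """An observed repaired junction, top strand, anchor to anchor."""

    id: str
    top: str
    assay: AssayConfig

    def __post_init__(self):
        object.__setattr__(self, "top", validate_bases(self.top, f"junction {self.id}"))
        a = self.assay
        if len(self.top) < len(a.left_anchor) + len(a.right_anchor):
            raise MalformedInputError(
                f"junction {self.id}: shorter than the two anchors combined"
            )
        if not self.top.startswith(a.left_anchor):
            raise MalformedInputError(f"junction {self.id}: anchor-missing (left)")
        if not self.top.endswith(a.right_anchor):
            raise MalformedInputError(f"junction {self.id}: anchor-missing (right)")


def apply_cut(duplex_top: str, site: CutSiteSpec) -> tuple[DsbEnd, DsbEnd]:
    """Cut a duplex at its unique recognition site into two 3'-overhung ends.

    The left end's top strand carries the final ``overhang_length`` bases
    before the protruding-strand scission as its 3' overhang; the right
    end's bottom strand carries the reverse complement of the same window.
    Religating the two ends with full annealing and no edits reconstructs
    ``duplex_top`` exactly.
    """
    duplex_top = validate_bases(duplex_top, "duplex_top")
    hits = [m.start() for m in re.finditer(re.escape(site.recognition), duplex_top)]
    if len(hits) != 1:
        raise AmbiguousCutError(
            f"{site.name}: recognition sequence found {len(hits)} times "
            f"(exactly one occurrence required)"
        )
    pos = hits[0]
    prot = pos + site.bottom_cut   # scission creating the 3'-protruding termini
    rec = pos + site.top_cut       # scission creating the recessed termini
    window = duplex_top[rec:prot]
    left = DsbEnd(
        side="left",
        duplex_top=duplex_top[:rec],
        overhang=window,
        overhang_strand="top",
    )
    right = DsbEnd(
        side="right",
        duplex_top=duplex_top[prot:],
        overhang=revcomp(window),
        overhang_strand="bottom",
    )
    return left, right


def religate(left: DsbEnd, right: DsbEnd) -> str:
    """Top strand produced by full annealing of two complementary ends.

    Requires the left overhang to equal the reverse complement of the right
    overhang (full 4-bp annealing, no edits).
    """
    if left.side != "left" or right.side != "right":
        raise AssayError("religate expects a (left, right) end pair")
    if left.overhang != revcomp(right.overhang):
        raise AssayError("ends are not fully complementary; cannot religate without edits")
    return left.duplex_top + left.overhang + right.duplex_top


# Cut-site geometries for the two endonucleases used by the assays.  Offsets
# follow REBASE: I-SceI cuts its 18-bp site leaving the 4-nt 3' overhang
# ATAA; HO cuts the MAT Y/Z junction (CGCAACA^GTATAA) leaving AACA.
ISCEI = CutSiteSpec(name="I-SceI", recognition="TAGGGATAACAGGGTAAT", top_cut=5, bottom_cut=9)
HO = CutSiteSpec(name="HO", recognition="CGCAACAGTATAA", top_cut=3, bottom_cut=7)


_REQUIRED_KEYS = (
    "name",
    "left.flank_top",
    "left.overhang",
    "right.overhang_bottom",
    "right.flank_top",
    "left_anchor",
    "right_anchor",
)


def _parse_flat(text: str) -> dict[str, str]:
    values: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key in values:
            raise ConfigError(f"line {lineno}: duplicate key {key!r}")
        values[key] = val.strip()
    return values


def load_assay(source: str | os.PathLike | io.TextIOBase) -> AssayConfig:
    """Load and validate an assay from flat key/value configuration text.

    ``source`` may be a path, a file object, or the configuration text
    itself (detected by the presence of newlines/'=').
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
    elif isinstance(source, os.PathLike) or (
        isinstance(source, str) and "=" not in source and "\n" not in source
    ):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = str(source)

    values = _parse_flat(text)
    missing = [k for k in _REQUIRED_KEYS if k not in values]
    if missing:
        raise ConfigError(f"missing required keys: {missing}")

    overhang_length = int(values.get("overhang_length", "4"))
    left_ov = validate_bases(values["left.overhang"], "left.overhang")
    right_ov = validate_bases(values["right.overhang_bottom"], "right.overhang_bottom")
    for what, ov in (("left", left_ov), ("right", right_ov)):
        if len(ov) != overhang_length:
            raise ConfigError(
                f"{what} overhang has length {len(ov)}, expected {overhang_length}"
            )

    left = DsbEnd(side="left", duplex_top=values["left.flank_top"],
                  overhang=left_ov, overhang_strand="top")
    right = DsbEnd(side="right", duplex_top=values["right.flank_top"],
                   overhang=right_ov, overhang_strand="bottom")

    karyotype = {}
    for key, val in values.items():
        if key.startswith("karyotype."):
            karyotype[key[len("karyotype."):]] = val

    return AssayConfig(
        name=values["name"],
        left_end=left,
        right_end=right,
        left_anchor=values["left_anchor"],
        right_anchor=values["right_anchor"],
        max_deletion=int(values.get("max_deletion", "25")),
        max_insertion=int(values.get("max_insertion", "6")),
        karyotype=karyotype,
    )


BUILTIN_ASSAYS = ("partial", "noncomp", "cis")


def builtin_assay(name: str, **overrides) -> AssayConfig:
    """Load one of the packaged assay definitions ('partial', 'noncomp', 'cis').

    Keyword overrides (e.g. ``max_deletion=30``) replace the corresponding
    fields after loading.
    """
    if name not in BUILTIN_ASSAYS:
        raise ConfigError(f"unknown builtin assay {name!r}; choose from {BUILTIN_ASSAYS}")
    ref = resources.files("nhejoin.data").joinpath(f"{name}_assay.cfg")
    cfg = load_assay(ref.read_text(encoding="utf-8"))
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg
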