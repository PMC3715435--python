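"""Translocated-chromosome size arithmetic.

Each parental chromosome is broken once; a reciprocal translocation joins
the left fragment of one chromosome to the right fragment of the other.
Sizes are handled in kb — junction-scale indels (tens of bp) vanish at
this resolution — so the module is deliberately small: interval
validation plus addition, the arithmetic used to predict the new bands on
a pulsed-field gel.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["KaryotypeError", "Chromosome", "KaryotypeModel", "translocated_sizes"]


class KaryotypeError(ValueError):
    pass


@dataclass(frozen=True)
class Chromosome:
    """A parental chromosome with a single break position (kb from left end)."""

    name: str
    length_kb: float
    break_kb: float

    def __post_init__(self):
        if not (0 < self.break_kb < self.length_kb):
            raise KaryotypeError(
                f"{self.name}: break at {self.break_kb} kb must lie strictly "
                f"inside (0, {self.length_kb})"
            )

    @property
    def left_kb(self) -> float:
        return self.break_kb

    @property
    def right_kb(self) -> float:
        return self.length_kb - self.break_kb


@dataclass(frozen=True)
class KaryotypeModel:
    """Broken chromosomes plus a perfect matching of their fragments.

    ``pairings`` lists products as (product_name, left_of, right_of): the
    left fragment of chromosome ``left_of`` joined to the right fragment
    of chromosome ``right_of``.  Every left and every right fragment must
    be used exactly once, so chromosomal material is conserved.
    """

    chromosomes: tuple[Chromosome, ...]
    pairings: tuple[tuple[str, str, str], ...]

    def __post_init__(self):
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise KaryotypeError("duplicate chromosome names")
        lefts = [p[1] for p in self.pairings]
        rights = [p[2] for p in self.pairings]
        if sorted(lefts) != sorted(names) or sorted(rights) != sorted(names):
            raise KaryotypeError(
                "pairings must use each chromosome's left and right fragment "
                "exactly once (unmatched fragment)"
            )

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KaryotypeError(f"unknown chromosome {name!r}")


def translocated_sizes(model: KaryotypeModel) -> list[tuple[str, float]]:
    """Size (kb) of each product: left-fragment plus right-fragment length."""
    out = []
    for product, left_of, right_of in model.pairings:
        size = model.chromosome(left_of).left_kb + model.chromosome(right_of).right_kb
        out.append((product, size))
    return out


def model_from_config(karyotype: dict) -> KaryotypeModel:
    """Build a model from the flat ``karyotype.*`` block of an assay file.

    Expected keys: ``chrom.<name> = <length_kb>,<break_kb>`` and
    ``product.<name> = <left_of>,<right_of>``.
    """
    chroms = []
    pairings = []
    for key, val in karyotype.items():
        if key.startswith("chrom."):
            length, brk = (float(x) for x in val.split(","))
            chroms.append(Chromosome(name=key[len("chrom."):], length_kb=length, break_kb=brk))
        elif key.startswith("product."):
            left_of, right_of = (x.strip() for x in val.split(","))
            pairings.append((key[len("product."):], left_of, right_of))
        else:
            raise KaryotypeError(f"unrecognised karyotype key {key!r}")
    return KaryotypeModel(chromosomes=tuple(chroms), pairings=tuple(pairings))
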