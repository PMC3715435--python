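"""Readers, writers and report rendering.

Junctions travel as FASTA (one record per translocant, id = colony label);
tabular outputs are TSV with a single ``#``-prefixed header comment that
records the package version and, where applicable, the seed, so a rerun
with identical inputs is byte-identical.  Summary tables render counts
first and percentages from counts (nearest integer), never the reverse.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, Sequence, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .assay import AssayConfig, Junction, MalformedInputError, validate_bases
from .explain import ClassifiedJunction, TypeDistribution, type_labels
from .simulate import SimulatedJunction
from .stats import PlatingExperiment

__all__ = [
    "read_junctions",
    "write_junctions",
    "write_truth",
    "read_plating_tsv",
    "classification_frame",
    "write_classification",
    "summary_frame",
    "render_summary_text",
    "write_json_report",
]


def _open_maybe(path_or_handle, mode="r"):
    if hasattr(path_or_handle, "read") or hasattr(path_or_handle, "write"):
        return path_or_handle, False
    return open(path_or_handle, mode, encoding="utf-8", newline=""), True


def read_junctions(
    source: str | os.PathLike | TextIO,
    assay: AssayConfig,
) -> tuple[list[Junction], list[tuple[str, str]]]:
    """Parse a junction FASTA against an assay.

    Returns (accepted junctions, rejects) where each reject is
    ``(record id, reason)``; records failing the anchor checks are
    rejected, while duplicate ids and alphabet violations raise, since
    they indicate a malformed file rather than an unexplainable junction.
    """
    handle, close = _open_maybe(source)
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if close:
            handle.close()
    seen: set[str] = set()
    junctions: list[Junction] = []
    rejects: list[tuple[str, str]] = []
    for rec in records:
        if rec.id in seen:
            raise MalformedInputError(f"duplicate junction id {rec.id!r}")
        seen.add(rec.id)
        seq = validate_bases(str(rec.seq), f"junction {rec.id}")  # raises on non-ACGT
        try:
            junctions.append(Junction(id=rec.id, top=seq, assay=assay))
        except MalformedInputError:
            rejects.append((rec.id, "anchor-missing"))
    return junctions, rejects


def write_junctions(
    dest: str | os.PathLike | TextIO,
    junctions: Iterable[Junction | SimulatedJunction],
) -> None:
    records = []
    for j in junctions:
        jj = j.junction if isinstance(j, SimulatedJunction) else j
        records.append(SeqRecord(Seq(jj.top), id=jj.id, description=""))
    handle, close = _open_maybe(dest, "w")
    try:
        SeqIO.write(records, handle, "fasta")
    finally:
        if close:
            handle.close()


def _header(seed: int | None = None) -> str:
    extra = "" if seed is None else f" seed={seed}"
    return f"# nhejoin {__version__}{extra}\n"


def write_truth(
    dest: str | os.PathLike | TextIO,
    cohort: Sequence[SimulatedJunction],
    seed: int | None = None,
) -> None:
    """Ground-truth labels and generating events for a simulated cohort."""
    handle, close = _open_maybe(dest, "w")
    try:
        handle.write(_header(seed))
        handle.write("id\ttruth_type\ttrim_left_prot\ttrim_right_rec\t"
                     "insertion_top\tmm_resolved_to\n")
        for sj in cohort:
            e = sj.truth_explanation
            mmr = "-" if e.mm_pos is None else "right"
            handle.write(
                f"{sj.junction.id}\t{sj.truth.label}\t{e.trim_left_prot}\t"
                f"{e.trim_right_rec}\t{e.insertion_top or '-'}\t{mmr}\n"
            )
    finally:
        if close:
            handle.close()


def read_plating_tsv(source: str | os.PathLike | TextIO) -> dict[str, list[PlatingExperiment]]:
    """Plating counts, one row per replicate.

    Columns: strain, sc, sgal, sgal_leu and optional dilution columns
    dil_sc, dil_sgal, dil_sgal_leu (default 1).
    """
    df = pd.read_csv(source, sep="\t", comment="#")
    required = {"strain", "sc", "sgal", "sgal_leu"}
    missing = required - set(df.columns)
    if missing:
        raise MalformedInputError(f"plating table lacks columns: {sorted(missing)}")
    out: dict[str, list[PlatingExperiment]] = {}
    for _, row in df.iterrows():
        exp = PlatingExperiment(
            colonies_sc=int(row["sc"]),
            colonies_sgal=int(row["sgal"]),
            colonies_sgal_leu=int(row["sgal_leu"]),
            dilution_sc=float(row.get("dil_sc", 1.0)),
            dilution_sgal=float(row.get("dil_sgal", 1.0)),
            dilution_sgal_leu=float(row.get("dil_sgal_leu", 1.0)),
        )
        out.setdefault(str(row["strain"]), []).append(exp)
    return out


def classification_frame(classified: Sequence[ClassifiedJunction]) -> pd.DataFrame:
    """Per-junction detail table (one row per junction, input order)."""
    rows = []
    for cj in classified:
        e = cj.explanation
        rows.append({
            "id": cj.junction_id,
            "type": cj.repair_type.label if cj.repair_type else "unclassifiable",
            "mh_len": e.mh_len if e else "-",
            "trim_left_prot": e.trim_left_prot if e else "-",
            "trim_left_rec": e.trim_left_rec if e else "-",
            "trim_right_prot": e.trim_right_prot if e else "-",
            "trim_right_rec": e.trim_right_rec if e else "-",
            "insertion_top": (e.insertion_top or "-") if e else "-",
            "templated_top": e.templated_top if e else "-",
            "templated_bottom": e.templated_bottom if e else "-",
            "mismatches_in_pairing": e.mismatches_in_pairing if e else "-",
            "alternates": cj.alternates,
            "ambiguous": cj.ambiguous,
        })
    return pd.DataFrame(rows)


def write_classification(
    dest: str | os.PathLike | TextIO,
    classified: Sequence[ClassifiedJunction],
    seed: int | None = None,
) -> None:
    handle, close = _open_maybe(dest, "w")
    try:
        handle.write(_header(seed))
        classification_frame(classified).to_csv(handle, sep="\t", index=False)
    finally:
        if close:
            handle.close()


def summary_frame(rows: Sequence[tuple[str, TypeDistribution]]) -> pd.DataFrame:
    """Cohort summary shaped like the published per-genotype tables.

    One row per strain/cohort: n sequenced, then one ``NN% (count)`` cell
    per repair type, plus any unclassifiable/ambiguous tallies.
    """
    if not rows:
        return pd.DataFrame()
    system = rows[0][1].system
    labels = type_labels(system)
    recs = []
    for strain, dist in rows:
        if dist.system != system:
            raise MalformedInputError("summary rows mix assay systems")
        pct = dist.percentages()
        rec = {"strain": strain, "n": dist.n}
        for lab in labels:
            if pct[lab] is None:
                rec[f"Type {lab}"] = "nd"
            else:
                rec[f"Type {lab}"] = f"{pct[lab]}% ({dist.counts[lab]})"
        rec["unclassifiable"] = dist.unclassifiable
        rec["ambiguous"] = dist.ambiguous
        recs.append(rec)
    return pd.DataFrame(recs)


def render_summary_text(rows: Sequence[tuple[str, TypeDistribution]]) -> str:
    """Fixed-width plain-text rendering of the summary table."""
    df = summary_frame(rows)
    if df.empty:
        return "(empty summary)\n"
    widths = {c: max(len(str(c)), *(len(str(v)) for v in df[c])) for c in df.columns}
    lines = ["  ".join(str(c).ljust(widths[c]) for c in df.columns)]
    for _, row in df.iterrows():
        lines.append("  ".join(str(row[c]).ljust(widths[c]) for c in df.columns))
    return "\n".join(lines) + "\n"


def write_json_report(
    dest: str | os.PathLike | TextIO,
    payload: dict,
    seed: int | None = None,
) -> None:
    """Deterministic JSON report (sorted keys, fixed separators)."""
    doc = {"nhejoin_version": __version__}
    if seed is not None:
        doc["seed"] = seed
    doc.update(payload)
    handle, close = _open_maybe(dest, "w")
    try:
        json.dump(doc, handle, indent=2, sort_keys=True)
        handle.write("\n")
    finally:
        if close:
            handle.close()
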