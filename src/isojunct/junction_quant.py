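"""Splice-junction-based isoform quantification of short-read RNA-seq.

The quantification never touches exonic coverage: everything is computed
from intron-spanning (junction-crossing) reads, which makes alternative
first-exon usage measurable with ordinary short reads.

Stages, in the order a pipeline applies them:

1. :func:`read_junction_tables` — parse per-sample junction count files
   (STAR ``SJ.out.tab`` dialect or a generic TSV) into one
   :class:`JunctionCountTable`;
2. :func:`annotate_junctions` — attach the gene model's Exon / Isoform
   labels by intron coordinates;
3. :func:`filter_junctions` — drop mitochondrial and non-canonical-motif
   junctions, and junctions detected in fewer than ``ceil(10% x samples)``
   samples;
4. :func:`normalize` — junction reads per million total junction-crossing
   reads in the respective sample (library-size correction);
5. :func:`summarize_by_exon` — pool splice-site variants sharing an exon
   label;
6. :func:`total_expression` — mean of the constitutive-backbone junction
   values (total gene output independent of promoter choice);
7. :func:`summarize_by_isoform` / :func:`isoform_composition` — sum the
   isoform-diagnostic junction signal and convert to percentages over the
   annotated isoforms per tissue/age group;
8. :func:`aggregate_groups` — group means with SEM.

:func:`point_region_counts` covers the one case a junction cannot: extended
internal exons whose upstream extension hosts a transcription start are
quantified by counting reads over a 1 bp window 2 bp upstream (transcript
5' direction) of the internal exon boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .gene_model import GeneModel
from .longread import LongReadAlignment

log = logging.getLogger("isojunct")

__all__ = [
    "JunctionCountTable",
    "NormalizedUsage",
    "IsoformComposition",
    "MITO_CONTIGS",
    "read_junction_tables",
    "write_star_sj",
    "annotate_junctions",
    "filter_junctions",
    "normalize",
    "summarize_by_exon",
    "summarize_by_isoform",
    "total_expression",
    "isoform_composition",
    "composition_frame",
    "aggregate_groups",
    "point_region_counts",
    "point_region_window",
]

#: contig names treated as mitochondrial DNA (configurable per call)
MITO_CONTIGS = frozenset({"chrM", "MT", "chrMT"})

#: STAR SJ.out.tab intron-motif codes: 0 = non-canonical, 1..6 = canonical
#: dinucleotide pairs (GT/AG, CT/AC, GC/AG, CT/GC, AT/AC, GT/AT)
_STAR_STRAND = {0: ".", 1: "+", 2: "-"}
_STAR_STRAND_REV = {"+": 1, "-": 2, ".": 0}


@dataclass
class JunctionCountTable:
    """Samples x junctions raw counts plus junction and sample metadata.

    ``counts``: DataFrame indexed by sample_id with one column per
    junction_id.  ``junctions``: per-junction metadata (contig,
    intron_start/intron_end 0-based half-open, strand, motif, annotated,
    exon_label, isoform_label).  ``samples``: per-sample metadata (species,
    tissue, age_group, dataset_id).  ``totals``: all junction-crossing reads
    per sample — the library-size denominator, deliberately kept independent
    of any later junction filtering.
    """

    counts: pd.DataFrame
    junctions: pd.DataFrame
    samples: pd.DataFrame
    totals: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def junction_ids(self) -> list[str]:
        return list(self.counts.columns)

    def validate(self) -> None:
        if list(self.counts.columns) != list(self.junctions.index):
            raise ValueError("counts columns and junction metadata disagree")
        if list(self.counts.index) != list(self.totals.index):
            raise ValueError("counts index and totals disagree")
        if not self.samples.index.is_unique:
            raise ValueError("duplicate sample_id in sample metadata")
        if (self.counts.values < 0).any():
            raise ValueError("negative junction counts")
        if (self.counts.sum(axis=1) > self.totals + 1e-9).any():
            raise ValueError("per-sample counts exceed total junction reads")


@dataclass
class NormalizedUsage:
    """Junction reads per million total junction-crossing reads."""

    values: pd.DataFrame  # samples x junctions
    junctions: pd.DataFrame
    samples: pd.DataFrame
    dropped_samples: tuple[str, ...] = ()


@dataclass(frozen=True)
class IsoformComposition:
    """Percentage composition over annotated isoforms for one group."""

    group: tuple
    percentages: Mapping[str, float]
    n_samples: int
    undefined: bool = False


# -------------------------------------------------------------------- input


def _star_junction_id(contig: str, start0: int, end0: int, strand: str) -> str:
    return f"{contig}:{start0}-{end0}:{strand}"


def read_junction_tables(
    paths: Sequence[str | Path],
    dialect: str = "star",
    sample_ids: Optional[Sequence[str]] = None,
    sample_meta: Optional[pd.DataFrame] = None,
) -> JunctionCountTable:
    """Read one junction count file per sample into a unified table.

    ``star`` dialect: STAR ``SJ.out.tab`` — 1-based inclusive intron
    coordinates, strand code (0/1/2), intron motif code (0 = non-canonical),
    annotated flag, unique-read count (used), multi-read count, overhang.
    ``tsv`` dialect: columns contig, donor, acceptor (1-based first/last
    intron base), strand, motif (canonical/non_canonical), count, optional
    total_junction_reads taken verbatim as the sample denominator.

    Per-sample totals default to the sum over all parsed junctions
    (genome-wide files make this the "all splice-junction crossing reads"
    denominator).
    """
    if dialect not in ("star", "tsv"):
        raise ValueError(f"unknown junction table dialect {dialect!r}")
    paths = [Path(p) for p in paths]
    if sample_ids is None:
        sample_ids = [p.name.removesuffix(".SJ.out.tab").removesuffix(".tsv") for p in paths]
    if len(sample_ids) != len(paths):
        raise ValueError("sample_ids and paths differ in length")

    per_sample: dict[str, pd.Series] = {}
    meta: dict[str, dict] = {}
    explicit_totals: dict[str, float] = {}
    for sid, path in zip(sample_ids, paths):
        if dialect == "star":
            frame = pd.read_csv(
                path,
                sep="\t",
                header=None,
                names=[
                    "contig",
                    "start1",
                    "end1",
                    "strand_code",
                    "motif_code",
                    "annotated",
                    "n_unique",
                    "n_multi",
                    "overhang",
                ],
            )
            frame["intron_start"] = frame["start1"] - 1
            frame["intron_end"] = frame["end1"]
            frame["strand"] = frame["strand_code"].map(_STAR_STRAND)
            frame["motif"] = np.where(frame["motif_code"] == 0, "non_canonical", "canonical")
            frame["count"] = frame["n_unique"]
            frame["annotated"] = frame["annotated"].astype(bool)
        else:
            frame = pd.read_csv(path, sep="\t")
            required = {"contig", "donor", "acceptor", "strand", "count"}
            missing = required - set(frame.columns)
            if missing:
                raise ValueError(f"{path}: generic TSV missing columns {sorted(missing)}")
            frame["intron_start"] = frame["donor"] - 1
            frame["intron_end"] = frame["acceptor"]
            if "motif" not in frame.columns:
                frame["motif"] = "canonical"
            if "annotated" not in frame.columns:
                frame["annotated"] = False
            if "total_junction_reads" in frame.columns:
                explicit_totals[sid] = float(frame["total_junction_reads"].iloc[0])
        ids = [
            _star_junction_id(c, a, b, s)
            for c, a, b, s in zip(
                frame["contig"], frame["intron_start"], frame["intron_end"], frame["strand"]
            )
        ]
        frame = frame.assign(junction_id=ids)
        per_sample[sid] = frame.set_index("junction_id")["count"]
        for _, row in frame.iterrows():
            meta.setdefault(
                row["junction_id"],
                {
                    "contig": row["contig"],
                    "intron_start": int(row["intron_start"]),
                    "intron_end": int(row["intron_end"]),
                    "strand": row["strand"],
                    "motif": row["motif"],
                    "annotated": bool(row["annotated"]),
                    "exon_label": "",
                    "isoform_label": "",
                },
            )

    counts = (
        pd.DataFrame(per_sample)
        .T.fillna(0)
        .astype(np.int64)
        .sort_index(axis=1)
        .reindex(list(sample_ids))
    )
    counts.index.name = "sample_id"
    junctions = pd.DataFrame.from_dict(meta, orient="index").loc[counts.columns]
    junctions.index.name = "junction_id"
    totals = counts.sum(axis=1).astype(float)
    for sid, t in explicit_totals.items():
        totals.loc[sid] = t
    if sample_meta is None:
        sample_meta = pd.DataFrame(
            {
                "sample_id": list(sample_ids),
                "species": "",
                "tissue": "",
                "age_group": "",
                "dataset_id": "",
            }
        ).set_index("sample_id")
    else:
        sample_meta = sample_meta.copy()
        if "sample_id" in sample_meta.columns:
            sample_meta = sample_meta.set_index("sample_id")
    table = JunctionCountTable(
        counts=counts, junctions=junctions, samples=sample_meta, totals=totals
    )
    table.validate()
    return table


def write_star_sj(table: JunctionCountTable, out_dir: str | Path) -> list[Path]:
    """Write one ``<sample>.SJ.out.tab`` per sample (inverse of the reader)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    motif_code = {"non_canonical": 0, "canonical": 1}
    written = []
    for sid in table.sample_ids:
        dest = out_dir / f"{sid}.SJ.out.tab"
        with dest.open("w") as fh:
            for jid, jrow in table.junctions.iterrows():
                count = int(table.counts.loc[sid, jid])
                fh.write(
                    "\t".join(
                        str(x)
                        for x in [
                            jrow["contig"],
                            jrow["intron_start"] + 1,
                            jrow["intron_end"],
                            _STAR_STRAND_REV.get(jrow["strand"], 0),
                            motif_code.get(jrow["motif"], 1),
                            int(bool(jrow["annotated"])),
                            count,
                            0,
                            30,
                        ]
                    )
                    + "\n"
                )
        written.append(dest)
    return written


def annotate_junctions(table: JunctionCountTable, model: GeneModel) -> JunctionCountTable:
    """Attach the model's Exon / Isoform columns by intron coordinates."""
    junctions = table.junctions.copy()
    by_coords = {
        (j.contig, j.intron_start, j.intron_end): j for j in model.junctions
    }
    for jid, row in junctions.iterrows():
        hit = by_coords.get((row["contig"], row["intron_start"], row["intron_end"]))
        if hit is not None:
            junctions.loc[jid, ["exon_label", "isoform_label", "annotated"]] = [
                hit.exon_label,
                hit.isoform_label or "",
                True,
            ]
    return JunctionCountTable(
        counts=table.counts, junctions=junctions, samples=table.samples, totals=table.totals
    )


# ------------------------------------------------------------------ filters


def filter_junctions(
    table: JunctionCountTable,
    detection_fraction: float = 0.10,
    mito_contigs: Iterable[str] = MITO_CONTIGS,
) -> JunctionCountTable:
    """Apply the junction-quality rules; totals are left untouched.

    Removes junctions on mitochondrial contigs and junctions with
    non-canonical intron motifs, then keeps only junctions detected
    (count > 0) in at least ``ceil(detection_fraction x n_samples)`` samples
    of the whole dataset.  Idempotent.
    """
    if table.counts.empty:
        raise ValueError("empty junction count table")
    if not 0 < detection_fraction <= 1:
        raise ValueError("detection_fraction must be in (0, 1]")
    mito = set(mito_contigs)
    keep = ~table.junctions["contig"].isin(mito)
    keep &= table.junctions["motif"] != "non_canonical"
    n_samples = len(table.counts.index)
    min_detected = math.ceil(detection_fraction * n_samples)
    detected = (table.counts > 0).sum(axis=0)
    keep &= detected.reindex(table.junctions.index).fillna(0) >= min_detected
    kept_ids = list(table.junctions.index[keep])
    return JunctionCountTable(
        counts=table.counts[kept_ids],
        junctions=table.junctions.loc[kept_ids],
        samples=table.samples,
        totals=table.totals,
    )


# -------------------------------------------------------------- arithmetic


def normalize(table: JunctionCountTable) -> NormalizedUsage:
    """Junction reads per million total junction-crossing reads per sample.

    Samples with zero total junction reads are dropped with a warning (not
    silently zero-divided).
    """
    zero = list(table.totals.index[table.totals <= 0])
    if zero:
        log.warning("dropping %d sample(s) with zero junction reads: %s", len(zero), zero)
    keep = [s for s in table.counts.index if s not in set(zero)]
    values = table.counts.loc[keep].div(table.totals.loc[keep], axis=0) * 1e6
    return NormalizedUsage(
        values=values,
        junctions=table.junctions,
        samples=table.samples.loc[[s for s in table.samples.index if s in set(keep)]],
        dropped_samples=tuple(zero),
    )


def summarize_by_exon(usage: NormalizedUsage, model: Optional[GeneModel] = None) -> pd.DataFrame:
    """Sum normalized values of junctions sharing an exon label.

    Splice-site variants of one junction (e.g. 7-8 variants I and II) pool
    into a single column.  Junctions with no exon label are ignored.
    """
    labels = usage.junctions["exon_label"]
    labelled = labels[labels != ""].index
    grouped = usage.values[list(labelled)].T.groupby(labels.loc[labelled]).sum().T
    return grouped.sort_index(axis=1)


def summarize_by_isoform(usage: NormalizedUsage) -> pd.DataFrame:
    """Sum normalized values of isoform-diagnostic junctions per isoform."""
    labels = usage.junctions["isoform_label"]
    labelled = labels[labels != ""].index
    grouped = usage.values[list(labelled)].T.groupby(labels.loc[labelled]).sum().T
    return grouped.sort_index(axis=1)


def total_expression(summary: pd.DataFrame, model: GeneModel) -> pd.Series:
    """Mean of the constitutive-chain junction summaries per sample.

    Uses the model's shared exon backbone (for the packaged gene, the ten
    junctions 10-11 .. 19-20), giving a total-gene-output measure that does
    not depend on which promoter each transcript used.
    """
    labels = model.constitutive_junction_labels
    missing = [lab for lab in labels if lab not in summary.columns]
    if missing:
        raise ValueError(
            f"constitutive junction label(s) missing from summary: {missing} "
            "(model/annotation mismatch)"
        )
    out = summary[labels].mean(axis=1)
    out.name = "total_expression"
    return out


def isoform_composition(
    iso_summary: pd.DataFrame,
    samples: pd.DataFrame,
    model: GeneModel,
    group_by: Sequence[str] = ("tissue", "age_group"),
    point_counts: Optional[pd.DataFrame] = None,
) -> list[IsoformComposition]:
    """Percentage isoform composition per sample group.

    Per group, each annotated isoform's diagnostic-junction signal (plus
    optional extended-exon point-region signal, same normalization) is
    averaged across the group's samples and divided by the sum over all
    annotated isoforms.  Groups with no signal are flagged undefined rather
    than emitting NaN percentages silently.
    """
    annotated = model.annotated_isoform_names
    values = iso_summary.reindex(columns=annotated, fill_value=0.0).astype(float)
    if point_counts is not None:
        values = values.add(point_counts.reindex_like(values).fillna(0.0), fill_value=0.0)
        values = values[annotated]
    meta = samples.loc[values.index]
    missing_cols = [g for g in group_by if g not in meta.columns]
    if missing_cols:
        raise ValueError(f"group_by columns missing from sample metadata: {missing_cols}")
    out: list[IsoformComposition] = []
    for group, idx in sorted(meta.groupby(list(group_by)).groups.items()):
        key = group if isinstance(group, tuple) else (group,)
        sub = values.loc[idx]
        means = sub.mean(axis=0)
        total = float(means.sum())
        if total <= 0:
            out.append(
                IsoformComposition(
                    group=key,
                    percentages={k: float("nan") for k in annotated},
                    n_samples=len(sub),
                    undefined=True,
                )
            )
            continue
        out.append(
            IsoformComposition(
                group=key,
                percentages={k: 100.0 * float(means[k]) / total for k in annotated},
                n_samples=len(sub),
            )
        )
    return out


def composition_frame(
    comps: Sequence[IsoformComposition], group_by: Sequence[str] = ("tissue", "age_group")
) -> pd.DataFrame:
    """Long-format table (group columns, isoform, percent, n_samples)."""
    rows = []
    for comp in comps:
        for isoform, pct in comp.percentages.items():
            row = dict(zip(group_by, comp.group))
            row.update(
                {
                    "isoform": isoform,
                    "percent": pct,
                    "n_samples": comp.n_samples,
                    "undefined": comp.undefined,
                }
            )
            rows.append(row)
    return pd.DataFrame(rows, columns=[*group_by, "isoform", "percent", "n_samples", "undefined"])


def aggregate_groups(
    values: pd.Series,
    samples: pd.DataFrame,
    group_by: Sequence[str] = ("tissue", "age_group"),
) -> pd.DataFrame:
    """Per-group mean and standard error of the mean.

    SEM = sd / sqrt(n) with the sample standard deviation; single-sample
    groups report SEM as missing (NaN), never zero.  Output order is
    independent of input sample order.
    """
    meta = samples.loc[values.index]
    frame = meta[list(group_by)].assign(value=values)
    grouped = frame.groupby(list(group_by))["value"]
    out = grouped.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] < 2, "sem"] = np.nan
    out = out.drop(columns="sd").sort_values(list(group_by)).reset_index(drop=True)
    return out


# ---------------------------------------------------------- point regions


def point_region_window(model: GeneModel, exon: str) -> tuple[str, int, int]:
    """Genomic 1 bp window 2 bp transcript-upstream of an internal exon start.

    ``exon`` may be an extended-exon name ("4c", "7bII") or the base exon
    name.  Returns (contig, start, end) 0-based half-open.
    """
    try:
        base, _ = model.resolve_extended_exon(exon)
    except KeyError:
        base = model.exon(exon)
        if not base.start_extensions:
            raise ValueError(
                f"exon {exon!r} has no extended-exon definition; "
                "point-region counting is defined for extended exons"
            )
    if model.strand == "+":
        pos = base.start - 3
    else:
        pos = base.end + 2
    return model.contig, pos, pos + 1


def point_region_counts(
    reads_by_sample: Mapping[str, Sequence[LongReadAlignment]],
    model: GeneModel,
    exon: str,
) -> pd.Series:
    """Reads overlapping the extended-exon point window, per sample.

    Each read is counted at most once regardless of its block structure.
    Samples with no alignments available should simply be absent from
    ``reads_by_sample``; composition is then computed without extended-exon
    signal for them.
    """
    contig, w_start, w_end = point_region_window(model, exon)
    out = {}
    for sid, reads in reads_by_sample.items():
        out[sid] = sum(
            1 for r in reads if r.contig == contig and r.overlaps(w_start, w_end)
        )
    return pd.Series(out, name=f"point_{exon}", dtype=np.int64)
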