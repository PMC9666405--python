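"""Gene models for multi-promoter genes with alternative 5' exons.

A :class:`GeneModel` describes one gene locus whose transcription can start
from many alternative first ("5'") exons, each of which selects a different
N-terminally distinct protein isoform of the same gene.  The motivating case
is the bHLH transcription factor gene *Tcf4*: a single locus with 13
alternative 5' exons, 18 internal exons and one long 3' terminal exon, whose
alternative promoters generate the isoforms TCF4-B, -C, -D, -A and -I that
dominate in brain tissue.

The model carries three layers of annotation that the analysis stages share:

* an exon catalogue (:class:`ExonDef`) with exon class (5' / internal / 3'),
  alternative splice-site variants (roman-numeral labels, e.g. the 12 bp
  acceptor extension that inserts the RSRS tetrapeptide) and optional
  5'-extended transcription-start regions ("extended exons" such as 4c and
  7bII, internal exons whose upstream extension hosts a transcription start);
* a splice-junction catalogue (:class:`Junction`) with per-junction
  exon labels ("3-4", "10-11", ...) and, for junctions unique to one
  transcript class, the isoform label used for isoform quantification;
* isoform definitions (:class:`IsoformDef`) binding initiating exons,
  diagnostic junctions and the full exon chain of each transcript.

All genomic coordinates are 0-based half-open on the forward genomic strand;
minus-strand genes are handled by recording the strand and interpreting
"upstream"/"downstream" transcript-wise.  Splice junctions are keyed by their
intron interval ``(contig, intron_start, intron_end, strand)`` in genomic
coordinates, so downstream code never special-cases the strand.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

__all__ = [
    "ExonClass",
    "SpliceVariant",
    "ExonDef",
    "IsoformDef",
    "Junction",
    "GeneModel",
    "GeneModelError",
    "GeneModelParseError",
    "GeneModelValidationError",
    "load_gene_model",
    "write_gene_model",
    "packaged_model_path",
]


class GeneModelError(Exception):
    """Base class for gene-model problems."""


class GeneModelParseError(GeneModelError):
    """The model file could not be parsed; the message names the record."""


class GeneModelValidationError(GeneModelError):
    """One or more model invariants are violated.

    ``failures`` lists every violation found, not just the first.
    """

    def __init__(self, failures: Sequence[str]):
        self.failures = list(failures)
        super().__init__(
            "gene model failed validation:\n  - " + "\n  - ".join(self.failures)
        )


class ExonClass(str, enum.Enum):
    FIVE_PRIME = "five_prime"
    INTERNAL = "internal"
    THREE_PRIME = "three_prime"


@dataclass(frozen=True)
class SpliceVariant:
    """Alternative donor/acceptor for one exon boundary.

    ``offset`` is in genomic bp relative to the canonical exon boundary
    (negative = the exon grows toward lower coordinates on a + strand gene).
    Labels follow the roman-numeral convention used for alternative splice
    sites in the gene diagrams.
    """

    label: str
    site: str  # "donor" or "acceptor", in transcript orientation
    offset: int


@dataclass(frozen=True)
class ExonDef:
    """One exon of the gene model.

    ``start_extensions`` maps a variant label to an upstream (transcript 5')
    extension in bp; an internal exon with an extension is an "extended exon"
    whose extension region can host a transcription start (e.g. exon 4 with
    extension label "c" is referred to as exon 4c).
    """

    name: str
    cls: ExonClass
    contig: str
    start: int
    end: int
    splice_variants: tuple[SpliceVariant, ...] = ()
    start_extensions: Mapping[str, int] = field(default_factory=dict)

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def extension_interval(self, label: str, strand: str) -> tuple[int, int]:
        """Genomic interval of the named upstream extension region."""
        ext = self.start_extensions[label]
        if strand == "+":
            return self.start - ext, self.start
        return self.end, self.end + ext


@dataclass(frozen=True)
class IsoformDef:
    """One N-terminally distinct protein isoform.

    ``initiating_exon`` is the exon housing the first in-frame start codon
    (an internal exon for isoforms like TCF4-D).  ``transcript_exons`` is the
    ordered exon chain of the canonical transcript encoding this isoform.
    ``extended_exon`` names an extended-exon transcription start (e.g.
    "7bII") quantified by point-region counting in short-read data.
    ``annotated`` marks isoforms included in composition denominators.
    """

    name: str
    initiating_exon: str
    diagnostic_junctions: frozenset[str]
    transcript_exons: tuple[str, ...]
    alt_initiating_exons: tuple[str, ...] = ()
    extended_exon: Optional[str] = None
    annotated: bool = True
    provisional: bool = False


@dataclass(frozen=True)
class Junction:
    """A splice junction between two annotated exons.

    ``donor``/``acceptor`` are transcript-orientation splice sites;
    ``intron_start``/``intron_end`` give the genomic intron interval
    (0-based half-open) regardless of strand.  ``exon_label`` pools
    splice-site variants of the same exon pair ("7-8" covers variants I and
    II); ``isoform_label`` is set only on junctions unique to one isoform.
    """

    contig: str
    strand: str
    up_exon: str
    down_exon: str
    intron_start: int
    intron_end: int
    exon_label: str
    junction_id: str
    variant: Optional[str] = None
    isoform_label: Optional[str] = None
    feature: Optional[str] = None  # e.g. "delta" for the exon-8/9 skip
    motif: str = "canonical"

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.contig, self.intron_start, self.intron_end, self.strand)


@dataclass
class GeneModel:
    """A validated multi-5'-exon gene model."""

    gene: str
    contig: str
    strand: str
    locus_start: int
    locus_end: int
    exons: tuple[ExonDef, ...]
    isoforms: tuple[IsoformDef, ...]
    junctions: tuple[Junction, ...]
    constitutive_chain: tuple[str, ...]
    splice_features: dict
    species: Optional[str] = None
    assembly: Optional[str] = None

    def __post_init__(self) -> None:
        self._exons_by_name = {e.name: e for e in self.exons}
        self._isoforms_by_name = {i.name: i for i in self.isoforms}
        self._junctions_by_key: dict[tuple, Junction] = {
            j.key: j for j in self.junctions
        }

    # ------------------------------------------------------------------ lookup

    def exon(self, name: str) -> ExonDef:
        try:
            return self._exons_by_name[name]
        except KeyError:
            raise KeyError(f"unknown exon label {name!r} in gene model {self.gene}")

    def isoform(self, name: str) -> IsoformDef:
        try:
            return self._isoforms_by_name[name]
        except KeyError:
            raise KeyError(f"unknown isoform {name!r} in gene model {self.gene}")

    @property
    def exon_names(self) -> list[str]:
        return [e.name for e in self.exons]

    @property
    def isoform_names(self) -> list[str]:
        return [i.name for i in self.isoforms]

    @property
    def annotated_isoform_names(self) -> list[str]:
        return [i.name for i in self.isoforms if i.annotated]

    @property
    def three_prime_exon(self) -> ExonDef:
        return next(e for e in self.exons if e.cls is ExonClass.THREE_PRIME)

    @property
    def five_prime_exons(self) -> list[ExonDef]:
        return [e for e in self.exons if e.cls is ExonClass.FIVE_PRIME]

    def junctions_between(self, a: str, b: str) -> list[Junction]:
        """All junctions joining exon ``a`` to exon ``b`` (transcript order).

        Splice-site variants of the same exon pair are returned as separate
        junctions.  Unknown labels raise ``KeyError``.
        """
        self.exon(a), self.exon(b)
        return [j for j in self.junctions if (j.up_exon, j.down_exon) == (a, b)]

    def junction_by_key(self, key: tuple[str, int, int, str]) -> Optional[Junction]:
        return self._junctions_by_key.get(key)

    def isoform_for_first_exon(self, exon: str) -> Optional[IsoformDef]:
        """Isoform selected by a transcript whose first exon is ``exon``.

        Resolves primary and alternative initiating 5' exons, internal exons
        that house an isoform's start codon, and extended-exon starts.
        Returns ``None`` for exons that initiate no known isoform (e.g. the
        3' terminal exon).
        """
        ex = self.exon(exon)  # raises for unknown labels
        for iso in self.isoforms:
            if iso.initiating_exon == exon or exon in iso.alt_initiating_exons:
                return iso
            if iso.extended_exon is not None:
                base, _ = self.resolve_extended_exon(iso.extended_exon)
                if base.name == exon:
                    return iso
            if iso.transcript_exons and iso.transcript_exons[0] == exon:
                return iso
        del ex
        return None

    def resolve_extended_exon(self, name: str) -> tuple[ExonDef, str]:
        """Resolve an extended-exon name like "4c" or "7bII".

        Returns the base exon and the extension label.
        """
        for exon in self.exons:
            for label in exon.start_extensions:
                if exon.name + label == name:
                    return exon, label
        raise KeyError(f"unknown extended exon {name!r} in gene model {self.gene}")

    def extended_exon_isoform(self, exon_name: str) -> Optional[IsoformDef]:
        """Isoform whose transcripts start in the named exon's extension."""
        for iso in self.isoforms:
            if iso.extended_exon is None:
                continue
            base, _ = self.resolve_extended_exon(iso.extended_exon)
            if base.name == exon_name:
                return iso
        return None

    # ------------------------------------------------------ derived structure

    @property
    def constitutive_junction_labels(self) -> list[str]:
        """Exon labels of the shared-backbone junctions, e.g. 10-11 ... 19-20."""
        chain = self.constitutive_chain
        return [f"{a}-{b}" for a, b in zip(chain[:-1], chain[1:])]

    def transcript_blocks(
        self,
        isoform: str,
        *,
        plus: bool = False,
        delta: bool = False,
        extended_start: bool = False,
        skip_exons: Iterable[str] = (),
    ) -> list[tuple[int, int]]:
        """Genomic exon blocks of one transcript, in transcript order.

        ``plus`` selects the alternative acceptor variant at the +/- splice
        region (the RSRS-encoding extension); ``delta`` drops the declared
        skippable exons (8-9); ``extended_start`` starts the transcript at the
        isoform's extended-exon upstream boundary; ``skip_exons`` removes
        arbitrary exons (used to fabricate aberrant reads).
        """
        iso = self.isoform(isoform)
        chain = [e for e in iso.transcript_exons if e not in set(skip_exons)]
        if delta:
            dropped = set(self.splice_features.get("delta", {}).get("skipped_exons", ()))
            if not dropped & set(chain):
                raise ValueError(f"isoform {isoform} has no delta-skippable exons")
            chain = [e for e in chain if e not in dropped]
        pm = self.splice_features.get("plus_minus", {})
        blocks: list[tuple[int, int]] = []
        for i, name in enumerate(chain):
            exon = self.exon(name)
            start, end = exon.start, exon.end
            if plus and name == pm.get("exon"):
                var = next(
                    v for v in exon.splice_variants if v.label == pm.get("plus_variant")
                )
                # acceptor variant moves the transcript-upstream exon edge
                if self.strand == "+":
                    start += var.offset
                else:
                    end -= var.offset
            if i == 0 and extended_start:
                if iso.extended_exon is None:
                    raise ValueError(f"isoform {isoform} has no extended exon")
                base, label = self.resolve_extended_exon(iso.extended_exon)
                if base.name != name:
                    raise ValueError(
                        f"extended exon {iso.extended_exon} is not the first exon of {isoform}"
                    )
                ext_start, ext_end = base.extension_interval(label, self.strand)
                if self.strand == "+":
                    start = ext_start
                else:
                    end = ext_end
            blocks.append((start, end))
        blocks.sort()
        if self.strand == "-":
            # transcript order for a minus-strand gene runs high -> low
            blocks = blocks[::-1]
        return blocks

    def junction_table(self) -> pd.DataFrame:
        """Junction annotation as a tidy table (the junction->Exon->Isoform map).

        Columns mirror the tab-delimited annotation interface: junction_id,
        contig, donor, acceptor (1-based first/last intron base), strand,
        exon_label (the "Exon column") and isoform_label (the "Isoform
        column").
        """
        rows = []
        for j in self.junctions:
            rows.append(
                {
                    "junction_id": j.junction_id,
                    "contig": j.contig,
                    "donor": j.intron_start + 1,
                    "acceptor": j.intron_end,
                    "strand": j.strand,
                    "up_exon": j.up_exon,
                    "down_exon": j.down_exon,
                    "exon_label": j.exon_label,
                    "isoform_label": j.isoform_label if j.isoform_label else "",
                    "feature": j.feature if j.feature else "",
                }
            )
        return pd.DataFrame(rows)

    # ------------------------------------------------------------- validation

    def validate(self) -> None:
        """Check every model invariant; raise listing all failures."""
        fail: list[str] = []
        names = [e.name for e in self.exons]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            fail.append(f"duplicated exon names: {dupes}")
        for e in self.exons:
            if not e.start < e.end:
                fail.append(f"exon {e.name}: start {e.start} !< end {e.end}")
            if not (self.locus_start <= e.start and e.end <= self.locus_end):
                fail.append(f"exon {e.name} outside locus bounds")
        n3 = sum(e.cls is ExonClass.THREE_PRIME for e in self.exons)
        if n3 != 1:
            fail.append(f"expected exactly one three_prime exon, found {n3}")
        if self.strand not in ("+", "-"):
            fail.append(f"strand must be '+' or '-', got {self.strand!r}")

        iso_names = [i.name for i in self.isoforms]
        if len(iso_names) != len(set(iso_names)):
            fail.append("duplicated isoform names")
        known_labels = {j.exon_label for j in self.junctions}
        for iso in self.isoforms:
            if not iso.diagnostic_junctions and iso.extended_exon is None:
                fail.append(
                    f"isoform {iso.name}: needs diagnostic junctions or an extended exon"
                )
            missing = sorted(set(iso.diagnostic_junctions) - known_labels)
            if missing:
                fail.append(f"isoform {iso.name}: diagnostic junctions {missing} not in model")
            for exname in (iso.initiating_exon, *iso.alt_initiating_exons):
                if exname not in self._exons_by_name:
                    fail.append(f"isoform {iso.name}: unknown initiating exon {exname!r}")
            for exname in iso.transcript_exons:
                if exname not in self._exons_by_name:
                    fail.append(f"isoform {iso.name}: unknown transcript exon {exname!r}")
            if iso.extended_exon is not None:
                try:
                    self.resolve_extended_exon(iso.extended_exon)
                except KeyError:
                    fail.append(f"isoform {iso.name}: unknown extended exon {iso.extended_exon!r}")

        for j in self.junctions:
            for exname in (j.up_exon, j.down_exon):
                if exname not in self._exons_by_name:
                    fail.append(f"junction {j.junction_id}: unknown exon {exname!r}")
            if not j.intron_start < j.intron_end:
                fail.append(f"junction {j.junction_id}: empty or inverted intron")
            if j.isoform_label and j.isoform_label not in self._isoforms_by_name:
                fail.append(
                    f"junction {j.junction_id}: orphan isoform label {j.isoform_label!r}"
                )
        jids = [j.junction_id for j in self.junctions]
        if len(jids) != len(set(jids)):
            fail.append("duplicated junction ids")

        # the constitutive chain must be a strict chain of existing junctions
        chain = self.constitutive_chain
        for a, b in zip(chain[:-1], chain[1:]):
            if a not in self._exons_by_name or b not in self._exons_by_name:
                fail.append(f"constitutive chain refers to unknown exon in {a}-{b}")
                continue
            if not any((j.up_exon, j.down_exon) == (a, b) for j in self.junctions):
                fail.append(f"constitutive chain junction {a}-{b} missing from model")

        # every adjacent pair in every transcript chain must be a junction
        pairs = {(j.up_exon, j.down_exon) for j in self.junctions}
        for iso in self.isoforms:
            for a, b in zip(iso.transcript_exons[:-1], iso.transcript_exons[1:]):
                if (a, b) not in pairs and all(
                    e in self._exons_by_name for e in (a, b)
                ):
                    fail.append(f"isoform {iso.name}: chain step {a}-{b} has no junction")

        if fail:
            raise GeneModelValidationError(fail)


# ---------------------------------------------------------------------- I/O


def _junction_coords(
    up: ExonDef, down: ExonDef, strand: str, donor_offset: int, acceptor_offset: int
) -> tuple[int, int]:
    """Genomic intron interval for a junction given in transcript order."""
    if strand == "+":
        return up.end + donor_offset, down.start + acceptor_offset
    # minus strand: the transcript-upstream exon sits at higher coordinates
    return down.end - acceptor_offset, up.start - donor_offset


def _build_junction(model_ctx: dict, spec: dict, exons: Mapping[str, ExonDef]) -> Junction:
    up_name, down_name = str(spec["up"]), str(spec["down"])
    try:
        up, down = exons[up_name], exons[down_name]
    except KeyError as e:
        raise GeneModelParseError(
            f"junction {spec!r}: unknown exon {e.args[0]!r}"
        ) from None
    strand = model_ctx["strand"]
    variant = spec.get("variant")
    donor_offset = acceptor_offset = 0
    if variant is not None:
        variant = str(variant)
        dv = next((v for v in up.splice_variants if v.label == variant and v.site == "donor"), None)
        av = next(
            (v for v in down.splice_variants if v.label == variant and v.site == "acceptor"),
            None,
        )
        if dv is None and av is None and variant != "I":
            raise GeneModelParseError(
                f"junction {up_name}-{down_name}: variant {variant!r} matches no "
                f"splice variant on either exon"
            )
        if dv is not None:
            donor_offset = dv.offset
        if av is not None:
            acceptor_offset = av.offset
    intron_start, intron_end = _junction_coords(up, down, strand, donor_offset, acceptor_offset)
    label = f"{up_name}-{down_name}"
    jid = label if variant is None else f"{label}.{variant}"
    return Junction(
        contig=model_ctx["contig"],
        strand=strand,
        up_exon=up_name,
        down_exon=down_name,
        intron_start=intron_start,
        intron_end=intron_end,
        exon_label=label,
        junction_id=jid,
        variant=variant,
        isoform_label=spec.get("isoform"),
        feature=spec.get("feature"),
        motif=spec.get("motif", "canonical"),
    )


def load_gene_model(path: str | Path) -> GeneModel:
    """Load and eagerly validate a gene model from a YAML config file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise GeneModelParseError(f"{path}: not valid YAML: {e}") from e
    if not isinstance(raw, dict):
        raise GeneModelParseError(f"{path}: expected a mapping at top level")

    for key in ("gene", "contig", "strand", "locus", "exons", "isoforms", "junctions"):
        if key not in raw:
            raise GeneModelParseError(f"{path}: missing required key {key!r}")

    exons: list[ExonDef] = []
    for rec in raw["exons"]:
        try:
            variants = tuple(
                SpliceVariant(str(v["label"]), str(v["site"]), int(v["offset"]))
                for v in rec.get("splice_variants", ())
            )
            exons.append(
                ExonDef(
                    name=str(rec["name"]),
                    cls=ExonClass(rec["class"]),
                    contig=str(raw["contig"]),
                    start=int(rec["start"]),
                    end=int(rec["end"]),
                    splice_variants=variants,
                    start_extensions={
                        str(k): int(v) for k, v in rec.get("start_extensions", {}).items()
                    },
                )
            )
        except (KeyError, ValueError, TypeError) as e:
            raise GeneModelParseError(f"{path}: malformed exon record {rec!r}: {e}") from e
    exon_map = {e.name: e for e in exons}

    isoforms: list[IsoformDef] = []
    for rec in raw["isoforms"]:
        try:
            isoforms.append(
                IsoformDef(
                    name=str(rec["name"]),
                    initiating_exon=str(rec["initiating_exon"]),
                    diagnostic_junctions=frozenset(
                        str(x) for x in rec.get("diagnostic_junctions", ())
                    ),
                    transcript_exons=tuple(str(x) for x in rec["transcript_exons"]),
                    alt_initiating_exons=tuple(
                        str(x) for x in rec.get("alt_initiating_exons", ())
                    ),
                    extended_exon=rec.get("extended_exon"),
                    annotated=bool(rec.get("annotated", True)),
                    provisional=bool(rec.get("provisional", False)),
                )
            )
        except (KeyError, ValueError, TypeError) as e:
            raise GeneModelParseError(f"{path}: malformed isoform record {rec!r}: {e}") from e

    ctx = {"contig": str(raw["contig"]), "strand": str(raw["strand"])}
    junctions = [_build_junction(ctx, dict(rec), exon_map) for rec in raw["junctions"]]

    locus = raw["locus"]
    model = GeneModel(
        gene=str(raw["gene"]),
        contig=ctx["contig"],
        strand=ctx["strand"],
        locus_start=int(locus[0]),
        locus_end=int(locus[1]),
        exons=tuple(exons),
        isoforms=tuple(isoforms),
        junctions=tuple(junctions),
        constitutive_chain=tuple(str(x) for x in raw.get("constitutive_chain", ())),
        splice_features=raw.get("splice_features", {}) or {},
        species=raw.get("species"),
        assembly=raw.get("assembly"),
    )
    model.validate()
    return model


def _model_to_dict(model: GeneModel) -> dict:
    out: dict = {
        "gene": model.gene,
    }
    if model.species:
        out["species"] = model.species
    if model.assembly:
        out["assembly"] = model.assembly
    out.update(
        {
            "contig": model.contig,
            "strand": model.strand,
            "locus": [model.locus_start, model.locus_end],
            "constitutive_chain": list(model.constitutive_chain),
            "splice_features": model.splice_features,
        }
    )
    ex_out = []
    for e in model.exons:
        rec: dict = {
            "name": e.name,
            "class": e.cls.value,
            "start": e.start,
            "end": e.end,
        }
        if e.splice_variants:
            rec["splice_variants"] = [
                {"label": v.label, "site": v.site, "offset": v.offset}
                for v in e.splice_variants
            ]
        if e.start_extensions:
            rec["start_extensions"] = dict(e.start_extensions)
        ex_out.append(rec)
    out["exons"] = ex_out
    iso_out = []
    for i in model.isoforms:
        rec = {
            "name": i.name,
            "initiating_exon": i.initiating_exon,
        }
        if i.alt_initiating_exons:
            rec["alt_initiating_exons"] = list(i.alt_initiating_exons)
        rec["diagnostic_junctions"] = sorted(i.diagnostic_junctions)
        if i.extended_exon:
            rec["extended_exon"] = i.extended_exon
        rec["transcript_exons"] = list(i.transcript_exons)
        rec["annotated"] = i.annotated
        if i.provisional:
            rec["provisional"] = True
        iso_out.append(rec)
    out["isoforms"] = iso_out
    j_out = []
    for j in model.junctions:
        rec = {"up": j.up_exon, "down": j.down_exon}
        if j.variant:
            rec["variant"] = j.variant
        if j.isoform_label:
            rec["isoform"] = j.isoform_label
        if j.feature:
            rec["feature"] = j.feature
        if j.motif != "canonical":
            rec["motif"] = j.motif
        j_out.append(rec)
    out["junctions"] = j_out
    return out


def write_gene_model(model: GeneModel, path: str | Path) -> None:
    """Write a model back to YAML in canonical key/record order.

    ``write_gene_model(load_gene_model(f), f2)`` produces a file that loads to
    an identical model, and writing an already-canonical file reproduces it
    byte for byte.
    """
    text = yaml.safe_dump(_model_to_dict(model), sort_keys=False, default_flow_style=None)
    Path(path).write_text(text)


def packaged_model_path(name: str = "tcf4_mouse") -> Path:
    """Path of a model YAML shipped with the package (tcf4_mouse, toy_three_exon)."""
    p = Path(__file__).parent / "data" / f"{name}.yaml"
    if not p.exists():
        raise FileNotFoundError(f"no packaged gene model named {name!r}")
    return p
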