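"""Readers/writers for the standard formats the pipeline touches.

Coordinates are 1-based inclusive everywhere (the GFF3 convention; the
Prodigal defline dialect is 1-based inclusive as well).  E-values are kept
exactly as parsed — zeros are floored to 1e-300 only at log-transform time,
inside :mod:`nuoscan.evalue_filtering`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed record in an input file; the message names the line."""


class RepliconType(str, Enum):
    CHROMOSOME = "chromosome"
    PLASMID = "plasmid"
    UNKNOWN = "unknown"


class AssemblyLevel(str, Enum):
    COMPLETE = "complete"
    CHROMOSOME = "chromosome"
    OTHER = "other"


@dataclass(frozen=True)
class GeneCall:
    """One predicted gene (CDS) with its placement on a replicon."""

    gene_id: str
    genome_id: str
    replicon_id: str
    start: int  # 1-based inclusive bp
    end: int  # 1-based inclusive bp
    strand: str  # "+" or "-"
    protein_length: int  # amino acids
    replicon_type: RepliconType = RepliconType.UNKNOWN

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.protein_length < 1:
            raise ValueError(f"gene {self.gene_id}: protein_length < 1")


@dataclass(frozen=True)
class HmmHit:
    """One profile-vs-protein match from an hmmsearch run.

    ``env_from``/``env_to`` are the 1-based amino-acid domain envelope within
    the target protein; they are only available from domtblout input.
    """

    gene_id: str
    profile: str
    evalue: float
    bitscore: float
    env_from: int | None = None
    env_to: int | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"hit {self.gene_id}/{self.profile}: evalue < 0")
        if (self.env_from is None) != (self.env_to is None):
            raise ValueError("envelope must give both ends or neither")
        if self.env_from is not None and not (1 <= self.env_from <= self.env_to):
            raise ValueError(
                f"hit {self.gene_id}/{self.profile}: bad envelope "
                f"{self.env_from}..{self.env_to}"
            )


@dataclass
class GenomeMetadata:
    genome_id: str
    assembly_level: AssemblyLevel = AssemblyLevel.OTHER
    contig_lengths: list[int] = field(default_factory=list)
    n50: int | None = None
    total_length: int | None = None
    n_contigs: int | None = None
    taxid: str = ""
    species: str = ""
    genus: str = ""
    phylum: str = ""
    class_: str = ""
    candidatus_flag: bool = False
    lifestyle: str | None = None


LIFESTYLES = ("aerobe", "anaerobe", "facultative_anaerobe", "microaerobe")

# HMMER 3.x fixed column layouts (whitespace-delimited; description is free text
# after the last fixed column).
_TBLOUT_NCOL = 18
_DOMTBLOUT_NCOL = 22


def _tokens(line: str, min_cols: int, lineno: int, path: str) -> list[str]:
    parts = line.split()
    if len(parts) < min_cols:
        raise ParseError(
            f"{path}:{lineno}: expected >= {min_cols} columns, got {len(parts)}"
        )
    return parts


def _parse_float(token: str, what: str, lineno: int, path: str) -> float:
    try:
        return float(token)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-numeric {what} {token!r}") from exc


def read_hmm_hits(path: str | Path, dialect: str = "tblout") -> list[HmmHit]:
    """Parse an HMMER3 ``--tblout`` or ``--domtblout`` file.

    Parameters
    ----------
    path:
        HMMER3 tabular output; ``#`` lines are comments.
    dialect:
        ``"tblout"`` (one row per target sequence; full-sequence e-value) or
        ``"domtblout"`` (one row per domain; carries the envelope coordinates).

    Returns one :class:`HmmHit` per data row.  For tblout, duplicate
    (gene_id, profile) rows keep the smallest e-value; domtblout rows are
    per-domain and all kept.
    """
    path = Path(path)
    if dialect not in ("tblout", "domtblout"):
        raise ValueError(f"unknown dialect {dialect!r}")
    hits: list[HmmHit] = []
    n_data = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_data += 1
            if dialect == "tblout":
                parts = _tokens(line, _TBLOUT_NCOL, lineno, str(path))
                hits.append(
                    HmmHit(
                        gene_id=parts[0],
                        profile=parts[2],
                        evalue=_parse_float(parts[4], "e-value", lineno, str(path)),
                        bitscore=_parse_float(parts[5], "score", lineno, str(path)),
                    )
                )
            else:
                parts = _tokens(line, _DOMTBLOUT_NCOL, lineno, str(path))
                env_from = int(_parse_float(parts[19], "env from", lineno, str(path)))
                env_to = int(_parse_float(parts[20], "env to", lineno, str(path)))
                hits.append(
                    HmmHit(
                        gene_id=parts[0],
                        profile=parts[3],
                        evalue=_parse_float(parts[6], "e-value", lineno, str(path)),
                        bitscore=_parse_float(parts[7], "score", lineno, str(path)),
                        env_from=env_from,
                        env_to=env_to,
                    )
                )
    if n_data == 0:
        logger.warning("%s: no data rows", path)
    if dialect == "tblout":
        hits = dedupe_hits(hits)
    return hits


def dedupe_hits(hits: Iterable[HmmHit]) -> list[HmmHit]:
    """Keep, for each (gene_id, profile) pair, the row with the smallest e-value."""
    best: dict[tuple[str, str], HmmHit] = {}
    order: list[tuple[str, str]] = []
    for hit in hits:
        key = (hit.gene_id, hit.profile)
        if key not in best:
            best[key] = hit
            order.append(key)
        elif hit.evalue < best[key].evalue:
            best[key] = hit
    return [best[k] for k in order]


def _replicon_type_for(
    replicon_id: str, replicon_types: dict[str, RepliconType | str] | None
) -> RepliconType:
    # Precedence: explicit metadata map > "plasmid" keyword in the id > unknown.
    if replicon_types and replicon_id in replicon_types:
        return RepliconType(replicon_types[replicon_id])
    if "plasmid" in replicon_id.lower():
        return RepliconType.PLASMID
    return RepliconType.UNKNOWN


def _protein_length_from_span(start: int, end: int) -> int:
    # CDS includes the stop codon, which encodes no residue.
    return (end - start + 1) // 3 - 1


def read_gene_calls(
    path: str | Path,
    dialect: str = "gff3",
    genome_id: str | None = None,
    replicon_types: dict[str, RepliconType | str] | None = None,
) -> list[GeneCall]:
    """Parse gene coordinates from GFF3 CDS features or Prodigal FASTA deflines.

    ``genome_id`` labels every returned gene; it defaults to the file stem.
    ``replicon_types`` optionally maps replicon ids to chromosome/plasmid;
    without it a replicon whose id contains the token "plasmid" is typed
    plasmid and everything else unknown.
    """
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    if dialect == "gff3":
        return _read_gff3(path, gid, replicon_types)
    if dialect == "prodigal_headers":
        return _read_prodigal_headers(path, gid, replicon_types)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_gff3(
    path: Path,
    genome_id: str,
    replicon_types: dict[str, RepliconType | str] | None,
) -> list[GeneCall]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneCall] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        if feat.end < feat.start:
            logger.warning("%s: CDS %s end < start, rejected", path, feat.id)
            continue
        if feat.strand not in ("+", "-"):
            raise ParseError(f"{path}: CDS {feat.id}: unknown strand {feat.strand!r}")
        ids = feat.attributes.get("ID", [feat.id])
        gid_attr = feat.attributes.get("genome_id", [])
        plen_attr = feat.attributes.get("protein_length", [])
        plen = (
            int(plen_attr[0])
            if plen_attr
            else _protein_length_from_span(feat.start, feat.end)
        )
        genes.append(
            GeneCall(
                gene_id=ids[0],
                genome_id=gid_attr[0] if gid_attr else genome_id,
                replicon_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                protein_length=plen,
                replicon_type=_replicon_type_for(feat.seqid, replicon_types),
            )
        )
    return genes


def _read_prodigal_headers(
    path: Path,
    genome_id: str,
    replicon_types: dict[str, RepliconType | str] | None,
) -> list[GeneCall]:
    from Bio import SeqIO

    genes: list[GeneCall] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        # Prodigal defline: >id # start # end # strand # key=value;...
        parts = [p.strip() for p in rec.description.split("#")]
        if len(parts) < 4:
            raise ParseError(f"{path}: defline {rec.id!r} not in Prodigal form")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric coordinates in {rec.id!r}") from exc
        if parts[3] == "1":
            strand = "+"
        elif parts[3] == "-1":
            strand = "-"
        else:
            raise ParseError(f"{path}: unknown strand symbol {parts[3]!r} in {rec.id!r}")
        if end < start:
            logger.warning("%s: gene %s end < start, rejected", path, rec.id)
            continue
        # Prodigal ids are <replicon>_<index>.
        replicon_id = rec.id.rsplit("_", 1)[0] if "_" in rec.id else rec.id
        genes.append(
            GeneCall(
                gene_id=rec.id,
                genome_id=genome_id,
                replicon_id=replicon_id,
                start=start,
                end=end,
                strand=strand,
                protein_length=_protein_length_from_span(start, end),
                replicon_type=_replicon_type_for(replicon_id, replicon_types),
            )
        )
    return genes


def curate_genomes(
    records: Sequence[GenomeMetadata],
) -> tuple[list[GenomeMetadata], dict[str, int]]:
    """Apply the genome-curation filters.

    Retains records with assembly level complete/chromosome, non-empty phylum
    and genus, and no Candidatus status.  Returns (retained, exclusion counts
    per rule); a record failing several rules is counted once per rule.
    """
    retained: list[GenomeMetadata] = []
    excluded = {"assembly_level": 0, "phylum": 0, "genus": 0, "candidatus": 0}
    for rec in records:
        bad = False
        if rec.assembly_level not in (AssemblyLevel.COMPLETE, AssemblyLevel.CHROMOSOME):
            excluded["assembly_level"] += 1
            bad = True
        if not rec.phylum:
            excluded["phylum"] += 1
            bad = True
        if not rec.genus:
            excluded["genus"] += 1
            bad = True
        if rec.candidatus_flag:
            excluded["candidatus"] += 1
            bad = True
        if not bad:
            retained.append(rec)
    return retained, excluded


_METADATA_COLUMNS = [
    "genome_id",
    "assembly_level",
    "contig_lengths",
    "taxid",
    "species",
    "genus",
    "phylum",
    "class",
    "candidatus_flag",
    "lifestyle",
]


def read_metadata(path: str | Path) -> list[GenomeMetadata]:
    """Read the per-genome metadata TSV.

    Expected columns: genome_id, assembly_level, contig_lengths (comma-joined
    bp) or n50/total_length/n_contigs, taxid, species, genus, phylum, class,
    candidatus_flag, lifestyle (optional/empty allowed).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records: list[GenomeMetadata] = []
    for _, row in df.iterrows():
        lengths = (
            [int(x) for x in str(row.get("contig_lengths", "")).split(",") if x]
            if row.get("contig_lengths", "")
            else []
        )
        if lengths and any(x <= 0 for x in lengths):
            raise ParseError(
                f"{path}: genome {row['genome_id']}: non-positive contig length"
            )
        level = str(row.get("assembly_level", "other")).lower() or "other"
        records.append(
            GenomeMetadata(
                genome_id=row["genome_id"],
                assembly_level=AssemblyLevel(level)
                if level in ("complete", "chromosome")
                else AssemblyLevel.OTHER,
                contig_lengths=lengths,
                n50=int(row["n50"]) if row.get("n50", "") else None,
                total_length=int(row["total_length"])
                if row.get("total_length", "")
                else None,
                n_contigs=int(row["n_contigs"]) if row.get("n_contigs", "") else None,
                taxid=row.get("taxid", ""),
                species=row.get("species", ""),
                genus=row.get("genus", ""),
                phylum=row.get("phylum", ""),
                class_=row.get("class", ""),
                candidatus_flag=str(row.get("candidatus_flag", "")).lower()
                in ("true", "1", "yes"),
                lifestyle=row.get("lifestyle") or None,
            )
        )
    return records


def write_metadata(records: Sequence[GenomeMetadata], path: str | Path) -> None:
    rows = []
    for rec in sorted(records, key=lambda r: r.genome_id):
        rows.append(
            {
                "genome_id": rec.genome_id,
                "assembly_level": rec.assembly_level.value,
                "contig_lengths": ",".join(str(x) for x in rec.contig_lengths),
                "taxid": rec.taxid,
                "species": rec.species,
                "genus": rec.genus,
                "phylum": rec.phylum,
                "class": rec.class_,
                "candidatus_flag": str(rec.candidatus_flag).lower(),
                "lifestyle": rec.lifestyle or "",
            }
        )
    pd.DataFrame(rows, columns=_METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path, sort_by: list[str] | None = None) -> None:
    """Write a result table as TSV with a header row and deterministic order.

    Columns keep their given order; rows are sorted by ``sort_by`` (default:
    all columns, left to right) so repeated runs are byte-identical.
    """
    out = df.copy()
    keys = sort_by if sort_by is not None else list(out.columns)
    if keys and len(out):
        out = out.sort_values(keys, kind="mergesort")
    out.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def gene_index(genes: Iterable[GeneCall]) -> dict[str, GeneCall]:
    """Index genes by gene_id, enforcing (genome_id, gene_id) uniqueness."""
    index: dict[str, GeneCall] = {}
    for gene in genes:
        key = gene.gene_id
        if key in index and index[key].genome_id == gene.genome_id:
            raise ValueError(f"duplicate gene_id {key} in genome {gene.genome_id}")
        index[key] = gene
    return index


def apply_replicon_types(
    genes: Sequence[GeneCall], replicon_types: dict[str, RepliconType | str]
) -> list[GeneCall]:
    """Re-type replicons from an explicit metadata map (overrides keyword typing)."""
    out = []
    for g in genes:
        if g.replicon_id in replicon_types:
            out.append(g if g.replicon_type == RepliconType(replicon_types[g.replicon_id])
                       else replace(g, replicon_type=RepliconType(replicon_types[g.replicon_id])))
        else:
            out.append(g)
    return out
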