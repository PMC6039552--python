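"""Genome, annotation and count-table I/O plus cytosine-context classification.

Coordinates are 0-based half-open everywhere inside the package.  Text outputs
use the conventions of the formats they imitate: cytosine-report TSVs carry
1-based inclusive positions (as Bismark does) and BED output is 0-based
half-open.

A cytosine "site" is strand specific: the C on the plus strand and the C that
the complementary G represents on the minus strand are two independent sites,
each classified into the CG / CHG / CHH context by the two bases immediately
downstream *on its own strand* (H = A, C or T).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

Strand = Literal["+", "-"]
Context = Literal["CG", "CHG", "CHH"]

CONTEXTS: tuple[Context, ...] = ("CG", "CHG", "CHH")
REGIONS: tuple[str, ...] = ("gene_body", "upstream", "downstream", "intergenic")

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: column order of the 7-column cytosine-report TSV
COUNTS_COLUMNS = [
    "replicon",
    "pos",
    "strand",
    "count_methylated",
    "count_unmethylated",
    "context",
    "trinucleotide",
]


class FastaParseError(ValueError):
    """Raised when a genome FASTA cannot be parsed."""


@dataclass
class Genome:
    """An ordered collection of replicon sequences (chromosome + plasmids).

    Sequences are stored uppercase and may contain only A/C/G/T/N.
    """

    replicons: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.replicons.items():
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"replicon {name!r} contains invalid characters: {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.replicons.items()}

    @property
    def names(self) -> list[str]:
        return list(self.replicons)

    def __len__(self) -> int:
        return sum(len(s) for s in self.replicons.values())

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        return read_genome(path)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.replicons.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)


def read_genome(path: str | Path) -> Genome:
    """Read a genome FASTA; sequences are uppercased, order preserved.

    Raises :class:`FastaParseError` naming the offending line when the file
    does not look like FASTA.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header '>' "
                    f"before sequence data"
                )
            break
        else:
            raise FastaParseError(f"{path}: empty file, no FASTA records")

    replicons: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in replicons:
            raise FastaParseError(f"{path}: duplicate replicon id {record.id!r}")
        replicons[record.id] = str(record.seq).upper()
    return Genome(replicons)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_context(
    genome: Genome, replicon: str, pos: int, strand: Strand
) -> Context | None:
    """Context (CG/CHG/CHH) of the cytosine at a strand-specific position.

    The classification looks at the two bases immediately downstream on the
    cytosine's own strand: CG if the first is G, else CHG if the second is G,
    else CHH.  Returns ``None`` when fewer than two downstream bases exist
    (replicon edge) or either downstream base is N.

    Raises ``ValueError`` if the base at (replicon, pos, strand) is not C.
    """
    seq = genome.replicons[replicon]
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(
                f"base at {replicon}:{pos}(+) is {seq[pos]!r}, not C"
            )
        down = seq[pos + 1 : pos + 3]
    elif strand == "-":
        # a C on the minus strand is a G on the stored forward sequence
        if seq[pos] != "G":
            raise ValueError(
                f"base at {replicon}:{pos}(-) is {seq[pos].translate(_COMPLEMENT)!r},"
                " not C"
            )
        down = seq[max(pos - 2, 0) : pos][::-1].translate(_COMPLEMENT)
    else:
        raise ValueError(f"unknown strand {strand!r}")
    if len(down) < 2 or "N" in down:
        return None
    if down[0] == "G":
        return "CG"
    if down[1] == "G":
        return "CHG"
    return "CHH"


def _byte_lookup(mapping: Mapping[str, str]) -> np.ndarray:
    table = np.zeros(256, dtype=np.uint8)
    for src, dst in mapping.items():
        table[ord(src)] = ord(dst)
    return table


_COMP_TABLE = _byte_lookup({"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"})


def enumerate_cytosines(genome: Genome) -> pd.DataFrame:
    """All strand-specific cytosines with a defined context.

    Returns a DataFrame with columns ``replicon, pos, strand, context,
    trinucleotide`` sorted by (replicon order, pos, strand); cytosines within
    2 bp of a replicon end or whose downstream dinucleotide touches an N are
    excluded (context undefined).
    """
    frames: list[pd.DataFrame] = []
    for name, seq in genome.replicons.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        length = arr.size
        for strand in ("+", "-"):
            if strand == "+":
                idx = np.flatnonzero(arr == ord("C"))
                idx = idx[idx <= length - 3]
                d1, d2 = arr[idx + 1], arr[idx + 2]
            else:
                idx = np.flatnonzero(arr == ord("G"))
                idx = idx[idx >= 2]
                d1 = _COMP_TABLE[arr[idx - 1]]
                d2 = _COMP_TABLE[arr[idx - 2]]
            keep = (d1 != ord("N")) & (d2 != ord("N"))
            idx, d1, d2 = idx[keep], d1[keep], d2[keep]
            context = np.where(
                d1 == ord("G"), "CG", np.where(d2 == ord("G"), "CHG", "CHH")
            )
            tri = np.char.add(
                "C",
                np.char.add(
                    d1.view("S1").astype("U1"), d2.view("S1").astype("U1")
                ),
            )
            frames.append(
                pd.DataFrame(
                    {
                        "replicon": name,
                        "pos": idx,
                        "strand": strand,
                        "context": context,
                        "trinucleotide": tri,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["replicon", "pos", "strand", "context", "trinucleotide"]
        )
    out = pd.concat(frames, ignore_index=True)
    out["replicon"] = pd.Categorical(
        out["replicon"], categories=genome.names, ordered=True
    )
    out = out.sort_values(["replicon", "pos", "strand"], kind="mergesort")
    out["replicon"] = out["replicon"].astype(str)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# feature annotation


@dataclass
class FeatureTable:
    """Gene and transposable-element intervals on the genome.

    ``genes``: DataFrame(replicon, start, end, strand, gene_id);
    ``tes``: DataFrame(replicon, start, end, te_id).  All intervals 0-based
    half-open.
    """

    genes: pd.DataFrame
    tes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["replicon", "start", "end", "te_id"]
        )
    )

    def __post_init__(self) -> None:
        for df, label in ((self.genes, "gene"), (self.tes, "TE")):
            if len(df) and (df["end"] <= df["start"]).any():
                raise ValueError(f"empty or inverted {label} interval")

    @classmethod
    def from_files(
        cls, gff3_path: str | Path, te_bed_path: str | Path | None = None
    ) -> "FeatureTable":
        genes = read_genes_gff3(gff3_path)
        tes = (
            read_te_bed(te_bed_path)
            if te_bed_path is not None
            else pd.DataFrame(columns=["replicon", "start", "end", "te_id"])
        )
        return cls(genes=genes, tes=tes)

    def gene_trees(self) -> dict[str, IntervalTree]:
        return _build_trees(self.genes, "gene_id")

    def te_trees(self) -> dict[str, IntervalTree]:
        return _build_trees(self.tes, "te_id")


def _build_trees(df: pd.DataFrame, id_col: str) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for rep, grp in df.groupby("replicon", sort=False):
        tree = IntervalTree()
        for start, end, ident in zip(grp["start"], grp["end"], grp[id_col]):
            tree[int(start) : int(end)] = ident
        trees[rep] = tree
    return trees


def read_genes_gff3(path: str | Path) -> pd.DataFrame:
    """Load ``gene`` features from a GFF3 file (coordinates made 0-based)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append(
            {
                "replicon": feat.seqid,
                "start": feat.start - 1,  # GFF3 is 1-based inclusive
                "end": feat.end,
                "strand": feat.strand,
                "gene_id": gene_id,
            }
        )
    return pd.DataFrame(rows, columns=["replicon", "start", "end", "strand", "gene_id"])


def write_genes_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.replicon}\tbsmeth\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


def read_te_bed(path: str | Path) -> pd.DataFrame:
    """Load TE intervals from a BED file (first 4+ columns used)."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2, 3],
            names=["replicon", "start", "end", "te_id"],
            dtype={"replicon": str, "start": int, "end": int, "te_id": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["replicon", "start", "end", "te_id"])
        df = df.astype({"start": int, "end": int})
    return df


def write_te_bed(tes: pd.DataFrame, path: str | Path) -> None:
    tes[["replicon", "start", "end", "te_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def _flank_interval(
    gene_start: int, gene_end: int, strand: str, length: int, side: str
) -> tuple[int, int]:
    """0-based half-open interval of a gene flank on the genome axis."""
    if (side == "upstream") == (strand != "-"):
        return max(gene_start - length, 0), gene_start
    return gene_end, gene_end + length


def assign_regions(
    sites: pd.DataFrame,
    features: FeatureTable,
    upstream_len: int = 100,
    downstream_len: int = 100,
) -> pd.DataFrame:
    """Assign every site to exactly one functional region.

    Precedence when regions overlap: gene_body > upstream > downstream >
    intergenic.  Returns a copy of ``sites`` with ``region`` and ``gene_id``
    columns (gene_id is NA for intergenic sites).
    """
    gene_trees = features.gene_trees()
    flank_trees: dict[str, dict[str, IntervalTree]] = {
        "upstream": {},
        "downstream": {},
    }
    for row in features.genes.itertuples(index=False):
        for side, length in (("upstream", upstream_len), ("downstream", downstream_len)):
            lo, hi = _flank_interval(row.start, row.end, row.strand, length, side)
            if hi > lo:
                tree = flank_trees[side].setdefault(row.replicon, IntervalTree())
                tree[lo:hi] = row.gene_id

    regions: list[str] = []
    gene_ids: list[object] = []
    for rep, pos in zip(sites["replicon"], sites["pos"]):
        pos = int(pos)
        hits = gene_trees.get(rep, IntervalTree())[pos]
        if hits:
            regions.append("gene_body")
            gene_ids.append(min(iv.data for iv in hits))
            continue
        for side in ("upstream", "downstream"):
            hits = flank_trees[side].get(rep, IntervalTree())[pos]
            if hits:
                regions.append(side)
                gene_ids.append(min(iv.data for iv in hits))
                break
        else:
            regions.append("intergenic")
            gene_ids.append(pd.NA)
    out = sites.copy()
    out["region"] = regions
    out["gene_id"] = gene_ids
    return out


def assign_region(
    site: tuple[str, int],
    features: FeatureTable,
    upstream_len: int = 100,
    downstream_len: int = 100,
) -> tuple[str, object]:
    """Region label and gene id for a single (replicon, pos) site."""
    df = pd.DataFrame({"replicon": [site[0]], "pos": [site[1]]})
    res = assign_regions(df, features, upstream_len, downstream_len)
    return res["region"].iloc[0], res["gene_id"].iloc[0]


# ---------------------------------------------------------------------------
# cytosine-report count tables


class CountsTableError(ValueError):
    """Raised for malformed rows in a cytosine-report count table."""


def read_counts_table(path: str | Path) -> pd.DataFrame:
    """Read a 7-column cytosine-report TSV.

    File columns: replicon, 1-based position, strand, methylated count,
    unmethylated count, context, trinucleotide.  Positions are converted to
    0-based internally.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=COUNTS_COLUMNS,
            dtype={
                "replicon": str,
                "strand": str,
                "context": str,
                "trinucleotide": str,
            },
        )
    except ValueError as exc:
        raise CountsTableError(f"{path}: cannot parse counts table: {exc}") from exc

    for col in ("pos", "count_methylated", "count_unmethylated"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise CountsTableError(
                f"{path}: line {line}: non-integer value in column {col!r}"
            )
        df[col] = numeric.astype(np.int64)

    for col, allowed in (
        ("strand", {"+", "-"}),
        ("context", set(CONTEXTS)),
    ):
        bad = ~df[col].isin(allowed)
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise CountsTableError(
                f"{path}: line {line}: unknown {col} token {df[col].iloc[line - 1]!r}"
            )

    neg = (df["count_methylated"] < 0) | (df["count_unmethylated"] < 0) | (df["pos"] < 1)
    if neg.any():
        line = int(neg.idxmax()) + 1
        raise CountsTableError(f"{path}: line {line}: negative count or position")

    df["pos"] = df["pos"] - 1
    return df


def write_counts_table(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a counts DataFrame back to the 7-column 1-based TSV format."""
    out = counts[COUNTS_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


def write_sites_bed(sites: pd.DataFrame, path: str | Path, score_col: str | None = None) -> None:
    """Write sites as BED6 (0-based half-open, single-base intervals)."""
    bed = pd.DataFrame(
        {
            "chrom": sites["replicon"],
            "start": sites["pos"],
            "end": sites["pos"] + 1,
            "name": sites.get("context", "."),
            "score": sites[score_col] if score_col else 0,
            "strand": sites["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
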