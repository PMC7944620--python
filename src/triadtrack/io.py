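"""Readers and writers for the pipeline's external file contracts.

Inputs are plain TSV / BED / GFF3 text. All genomic intervals are
normalised on read to 0-based half-open coordinates: BED input passes
through unchanged, GFF3 (1-based closed) is shifted. Every downstream
module consumes only the in-memory objects produced here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

logger = logging.getLogger("triadtrack")

#: Allowed chromosomal-zone labels: distal ends (R1, R3), interstitial
#: arms (R2a, R2b) and the proximal centromeric/pericentromeric zone (C).
ZONES = ("R1", "R2a", "C", "R2b", "R3")

SUBGENOMES = ("A", "B", "D")


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.Series:
    """Read a two-column ``gene_id<TAB>count`` table into a Series.

    Counts must be non-negative integers; a duplicated gene_id is an
    error.  A header-only file yields an empty Series (with a warning).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene_id, count)")
    df = df.iloc[:, :2]
    df.columns = ["gene_id", "count"]
    if df.empty:
        logger.warning("%s: no data rows (header only)", path)
        return pd.Series(dtype=int, name="count")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    counts = pd.to_numeric(df["count"], errors="raise")
    if (counts < 0).any():
        bad = df.loc[counts < 0, "gene_id"].iloc[0]
        raise ValueError(f"{path}: negative count for gene {bad!r}")
    if (counts != counts.round()).any():
        bad = df.loc[counts != counts.round(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: non-integer count for gene {bad!r}")
    out = pd.Series(counts.astype(int).values, index=df["gene_id"].values,
                    name="count")
    out.index.name = "gene_id"
    return out


# ---------------------------------------------------------------------------
# gene models (GFF3 / BED)
# ---------------------------------------------------------------------------

def _read_bed_genes(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "gene_id"],
                     usecols=[0, 1, 2, 3],
                     dtype={"chrom": str, "gene_id": str})
    return df


def _read_gff3_genes(path: Path) -> pd.DataFrame:
    """Light GFF3 parser: gene features only, ID= from column 9.

    GFF3 is 1-based closed; converted here to 0-based half-open.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("gene_id")
            if gid is None:
                raise ValueError(f"{path}: gene feature without ID attribute")
            gid = gid.removeprefix("gene:")
            rows.append((parts[0], int(parts[3]) - 1, int(parts[4]), gid))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def read_gene_coords(path: str | Path) -> pd.DataFrame:
    """Read gene coordinates from GFF3 or BED, 0-based half-open.

    Returns a frame indexed by gene_id with columns chrom, start, end,
    length (= end - start).
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        df = _read_gff3_genes(path)
    else:
        df = _read_bed_genes(path)
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene {dup!r}")
    df = df.set_index("gene_id")
    df["length"] = df["end"] - df["start"]
    if (df["length"] <= 0).any():
        bad = df.index[df["length"] <= 0][0]
        raise ValueError(f"{path}: non-positive length for gene {bad!r}")
    return df


# ---------------------------------------------------------------------------
# triad table
# ---------------------------------------------------------------------------

@dataclass
class TriadTable:
    """The 1:1:1 A/B/D homoeolog mapping with gene coordinates.

    ``table`` is indexed by triad_id with columns gene_A/gene_B/gene_D;
    ``coords`` is indexed by gene_id (chrom, start, end, length).
    """

    table: pd.DataFrame
    coords: pd.DataFrame

    def __post_init__(self) -> None:
        genes = self.table[["gene_A", "gene_B", "gene_D"]].values.ravel()
        dup = pd.Series(genes)[pd.Series(genes).duplicated()]
        if len(dup):
            raise ValueError(f"gene {dup.iloc[0]!r} appears in two triads")
        missing = set(genes) - set(self.coords.index)
        if missing:
            raise ValueError(
                f"gene {sorted(missing)[0]!r} has no coordinates")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate triad_id")

    def __len__(self) -> int:
        return len(self.table)

    def genes(self, subgenome: str) -> pd.Series:
        """Gene ids of one subgenome, indexed by triad_id."""
        return self.table[f"gene_{subgenome}"]

    def gene_lengths(self) -> pd.Series:
        return self.coords["length"]

    def gene_map(self) -> pd.DataFrame:
        """Long form: one row per gene (triad_id, subgenome)."""
        frames = []
        for sub in SUBGENOMES:
            frames.append(pd.DataFrame({
                "gene_id": self.table[f"gene_{sub}"].values,
                "triad_id": self.table.index,
                "subgenome": sub,
            }))
        return pd.concat(frames, ignore_index=True).set_index("gene_id")

    def midpoints(self) -> pd.DataFrame:
        """Per-gene midpoint floor((start+end)/2), used for zone lookup."""
        mid = (self.coords["start"] + self.coords["end"]) // 2
        return pd.DataFrame({"chrom": self.coords["chrom"],
                             "midpoint": mid})


def read_triads(path: str | Path, coords: pd.DataFrame) -> TriadTable:
    """Read the triad mapping TSV and join gene coordinates."""
    df = pd.read_csv(path, sep="\t",
                     dtype={"triad_id": str, "gene_A": str,
                            "gene_B": str, "gene_D": str})
    required = {"triad_id", "gene_A", "gene_B", "gene_D"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    return TriadTable(df.set_index("triad_id"), coords)


# ---------------------------------------------------------------------------
# chromosomal zone partition
# ---------------------------------------------------------------------------

def validate_zones(df: pd.DataFrame) -> pd.DataFrame:
    bad = set(df["zone"]) - set(ZONES)
    if bad:
        raise ValueError(f"unknown zone label(s): {sorted(bad)}")
    for chrom, grp in df.groupby("chrom"):
        grp = grp.sort_values("start")
        if (grp["end"].values[:-1] > grp["start"].values[1:]).any():
            raise ValueError(f"overlapping zone intervals on {chrom}")
        if (grp["end"] <= grp["start"]).any():
            raise ValueError(f"empty zone interval on {chrom}")
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def read_zones(path: str | Path) -> pd.DataFrame:
    """Read the BED-like zone partition (chrom, start, end, zone)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "zone"],
                     dtype={"chrom": str, "zone": str})
    return validate_zones(df)


# ---------------------------------------------------------------------------
# GO annotation
# ---------------------------------------------------------------------------

def read_go(path: str | Path) -> pd.DataFrame:
    """Read gene_id<TAB>term_id[<TAB>term_name] annotation."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    return df[["gene_id", "term_id", "term_name"]]


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Analysis configuration; thresholds default to the study's values."""

    counts: list = field(default_factory=list)   # [{genotype, assay, replicate, path}]
    triads: str | None = None
    genes: str | None = None
    zones: str | None = None
    go: str | None = None
    tau: float = 0.5            # modified-triad TPM threshold
    alpha: float = 0.05
    q_threshold: float = 0.05
    series: Mapping[str, list] = field(default_factory=lambda: {
        "domestication": ["WTW", "DTW", "ETW"],
        "ploidy": ["TAA10", "ETW", "XX329"],
    })


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# generic table output (round-trip safe)
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with stable float formatting."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
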