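"""Readers and writers for every on-disk format the pipeline touches.

Formats: BED-like probe annotation TSV, per-array two-channel intensity
TSVs, sample sheet TSV, GMT gene sets, miRNA->target map TSV, truth tables.
All genomic coordinates are 0-based half-open internally (BED convention at
the boundary).  Gene identifiers are matched exactly after upper-casing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GenomeLayout, SyntheticTruth

log = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "chromosome", "start", "end", "probe_id", "promoter_id",
    "gene_id", "cls", "strand", "tss", "offset",
]


class ParseError(ValueError):
    pass


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------- annotation

def write_probe_annotation(layout: GenomeLayout, path: str | Path) -> None:
    """BED-like TSV: chrom, start, end, probe_id, promoter_id, gene_id,
    class, strand, plus tss/offset columns so the layout round-trips."""
    probes = layout.probes.merge(
        layout.promoters[["promoter_id", "tss"]], on="promoter_id"
    )
    probes[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def load_probe_annotation(path: str | Path) -> GenomeLayout:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"cannot parse annotation {path}: {exc}") from exc
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"annotation {path} lacks columns {sorted(missing)}")
    for col in ("start", "end", "tss", "offset"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ParseError(
                f"annotation {path}: non-numeric {col} at line {bad[0] + 2}"
            )
        df[col] = df[col].astype(int)
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValidationError(
            f"annotation {path}: start >= end at line {bad[0] + 2}"
        )
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValidationError(f"duplicate probe_id {dup!r} in {path}")

    promoters = (
        df.groupby("promoter_id", sort=False)
        .agg(
            gene_id=("gene_id", "first"),
            chromosome=("chromosome", "first"),
            tss=("tss", "first"),
            strand=("strand", "first"),
            cls=("cls", "first"),
        )
        .reset_index()
        .sort_values(["chromosome", "tss"], kind="stable")
        .reset_index(drop=True)
    )
    promoters["block"] = -1
    chroms = [
        (c, int(df.loc[df["chromosome"] == c, "end"].max()))
        for c in promoters["chromosome"].unique()
    ]
    probes = df[
        ["probe_id", "promoter_id", "chromosome", "start", "end", "offset",
         "gene_id", "cls", "strand"]
    ].copy()
    return GenomeLayout(chroms, promoters, probes)


# ----------------------------------------------------------------- intensity

def write_arrays(
    bound: pd.DataFrame, input_: pd.DataFrame, sheet: pd.DataFrame, outdir: str | Path
) -> None:
    """One TSV per array (probe_id, Cy5_bound, Cy3_input) plus the sheet."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for array_id in sheet["array_id"]:
        pd.DataFrame(
            {
                "probe_id": bound.index,
                "Cy5_bound": bound[array_id].to_numpy(),
                "Cy3_input": input_[array_id].to_numpy(),
            }
        ).to_csv(outdir / f"{array_id}.tsv", sep="\t", index=False)
    write_sample_sheet(sheet, outdir / "sample_sheet.tsv")


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def load_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    required = {"array_id", "individual_id", "replicate", "group"}
    missing = required - set(sheet.columns)
    if missing:
        raise ParseError(f"sample sheet lacks columns {sorted(missing)}")
    if sheet["array_id"].duplicated().any():
        raise ValidationError("duplicate array_id in sample sheet")
    groups = set(sheet["group"])
    if len(groups) != 2:
        raise ValidationError(f"group labels must be binary, got {sorted(groups)}")
    return sheet


def load_arrays(
    intensity_dir: str | Path, sheet_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load and align all per-array intensity files listed in the sheet.

    Returns (bound, input, sheet) with probes aligned across arrays by
    probe_id; non-positive intensities become NaN (log-ratio undefined).
    """
    intensity_dir = Path(intensity_dir)
    sheet = load_sample_sheet(sheet_path)
    bound_cols, input_cols = {}, {}
    probe_index: pd.Index | None = None
    for array_id in sheet["array_id"]:
        path = intensity_dir / f"{array_id}.tsv"
        if not path.exists():
            raise ValidationError(f"missing intensity file for array {array_id}")
        df = pd.read_csv(path, sep="\t")
        df = df.set_index("probe_id")
        if probe_index is None:
            probe_index = df.index
            if probe_index.duplicated().any():
                raise ValidationError(f"duplicate probe_id in {path}")
        else:
            if set(df.index) != set(probe_index):
                offenders = sorted(set(df.index) ^ set(probe_index))[:10]
                raise ValidationError(
                    f"probe set mismatch in array {array_id}: {offenders}"
                )
            df = df.reindex(probe_index)
        for col, store in (("Cy5_bound", bound_cols), ("Cy3_input", input_cols)):
            v = df[col].to_numpy(dtype=float)
            n_bad = int((v <= 0).sum())
            if n_bad:
                log.warning("array %s: %d non-positive %s values flagged missing",
                            array_id, n_bad, col)
            store[array_id] = np.where(v > 0, v, np.nan)
    bound = pd.DataFrame(bound_cols, index=probe_index)
    input_ = pd.DataFrame(input_cols, index=probe_index)
    return bound, input_, sheet


# ----------------------------------------------------------------- gene sets

def load_gene_sets(
    path: str | Path, universe: set[str] | None = None
) -> dict[str, set[str]]:
    """Parse a GMT file (name, description, genes...).

    Gene ids are upper-cased.  When a universe is supplied, sets are
    intersected with it and sets left empty are dropped with a warning.
    """
    sets: dict[str, set[str]] = {}
    if universe is not None:
        universe = {g.upper() for g in universe}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >=3 fields")
            name, genes = fields[0], {g.upper() for g in fields[2:] if g}
            if not genes:
                raise ParseError(f"{path}:{lineno}: empty gene set {name!r}")
            if universe is not None:
                genes &= universe
                if not genes:
                    log.warning("gene set %s has no profiled genes; dropped", name)
                    continue
            sets[name] = genes
    return sets


def write_gene_sets(sets: dict[str, set[str]], path: str | Path, source: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, source, *sorted(genes)]) + "\n")


def load_mirna_targets(
    path: str | Path, universe: set[str] | None = None
) -> dict[str, set[str]]:
    """TSV with columns mirna_id, gene_id -> map miRNA -> target gene set."""
    df = pd.read_csv(path, sep="\t")
    if not {"mirna_id", "gene_id"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns mirna_id, gene_id")
    df["gene_id"] = df["gene_id"].str.upper()
    if universe is not None:
        universe = {g.upper() for g in universe}
        df = df[df["gene_id"].isin(universe)]
    out: dict[str, set[str]] = {}
    for mid, sub in df.groupby("mirna_id", sort=False):
        out[mid] = set(sub["gene_id"])
    return out


def write_mirna_targets(target_map: dict[str, set[str]], path: str | Path) -> None:
    rows = [
        (mid, gid) for mid in target_map for gid in sorted(target_map[mid])
    ]
    pd.DataFrame(rows, columns=["mirna_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


# --------------------------------------------------------------- truth/FASTA

def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    df = truth.dm_effects.rename_axis("promoter_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def load_truth(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("promoter_id")["delta"]


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
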