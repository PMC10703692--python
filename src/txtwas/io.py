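"""On-disk formats: TSV dialects, PLINK1 BED/BIM/FAM, YAML config, manifests.

All TSVs are tab-separated, UTF-8, '#'-comment aware. Coordinates are
1-based (PLINK/GWAS convention). Matrices are samples x features in memory.
Parsers fail loudly on malformed input; missing genotypes are mean-imputed
before standardization (logged) unless `on_missing="raise"`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import GenotypeMatrix, GwasSummary, LDMatrix
from .model import WeightModel
from .simulate import standardize

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes_tsv",
    "read_plink",
    "write_plink",
    "read_sumstats",
    "write_sumstats",
    "read_weights",
    "write_weights",
    "read_ld",
    "write_ld",
    "read_expression",
    "write_expression",
    "load_config",
    "write_manifest",
]

_SUMSTAT_COLS = ["snp", "chr", "pos", "a1", "a2", "z", "n"]
_WEIGHT_COLS = ["gene", "isoform", "snp", "a1", "a2", "weight", "cv_r2", "method"]


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kw)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"malformed TSV {path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _finalize_counts(
    G: np.ndarray, snps: pd.DataFrame, maf_min: float, on_missing: str
) -> GenotypeMatrix:
    G = G.astype(float)
    n_missing = int(np.isnan(G).sum())
    if n_missing:
        if on_missing == "raise":
            raise ValueError(f"{n_missing} missing genotype calls present")
        frac = n_missing / G.size
        logger.info("mean-imputing %d missing genotype calls (%.3f%%)", n_missing, 100 * frac)
        col_mean = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G[idx] = col_mean[idx[1]]
    freq = G.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    keep = (maf >= maf_min) & (G.std(axis=0) > 0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("MAF/monomorphic filter removed %d SNP(s)", dropped)
    G = G[:, keep]
    snps = snps.loc[keep].reset_index(drop=True)
    snps["maf"] = maf[keep]
    if G.shape[1] == 0:
        raise ValueError("no SNPs survive filtering")
    return GenotypeMatrix(X=standardize(G), snps=snps, counts=G, maf=maf[keep])


def read_genotypes(
    path, fmt: str = "tsv", maf_min: float = 0.0, on_missing: str = "impute"
) -> GenotypeMatrix:
    """Load a dosage panel from TSV (rows = samples, columns = SNP ids) or a
    PLINK1 BED/BIM/FAM prefix."""
    if fmt == "plink":
        return read_plink(path, maf_min=maf_min, on_missing=on_missing)
    with open(path, "rt", encoding="utf-8") as fh:
        header = ""
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n")
                break
    names = header.split("\t")
    dups = pd.Index(names)[pd.Index(names).duplicated()]
    if len(dups):
        raise ValueError(f"{path}: duplicated SNP id {dups[0]!r}")
    df = _read_tsv(path)
    if "sample" in df.columns:
        df = df.drop(columns=["sample"])
    G = df.to_numpy(dtype=float)
    snps = pd.DataFrame(
        {"snp": df.columns, "chr": 1, "pos": np.arange(1, len(df.columns) + 1), "a1": "A", "a2": "G"}
    )
    return _finalize_counts(G, snps, maf_min, on_missing)


def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    counts = genotypes.counts
    if counts is None:
        raise ValueError("genotype panel has no raw counts to write")
    pd.DataFrame(counts, columns=genotypes.snp_ids).to_csv(path, sep="\t", index=False)


# --- PLINK1 binary (2-bit) codec -------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# SNP-major 2-bit codes: 00=hom A1, 01=missing, 10=het, 11=hom A2
_CODE_TO_DOSAGE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}


def read_plink(prefix, maf_min: float = 0.0, on_missing: str = "impute") -> GenotypeMatrix:
    """Read a PLINK1 BED/BIM/FAM triplet; dosages count the BIM A1 allele."""
    prefix = Path(prefix)
    bim = _read_tsv(
        prefix.with_suffix(".bim"), header=None,
        names=["chr", "snp", "cm", "pos", "a1", "a2"],
    )
    fam = _read_tsv(
        prefix.with_suffix(".fam"), header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
    )
    if bim["snp"].duplicated().any():
        dup = bim.loc[bim["snp"].duplicated(), "snp"].iloc[0]
        raise ValueError(f"duplicated SNP id in BIM: {dup!r}")
    same = bim["a1"].astype(str) == bim["a2"].astype(str)
    if same.any():
        raise ValueError(f"identical alleles in BIM for {bim.loc[same, 'snp'].iloc[0]!r}")
    n, p = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK1 BED)")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * p
    if len(raw) != expected:
        raise ValueError(f"{prefix}.bed: truncated (got {len(raw)} bytes, expected {expected})")
    data = np.frombuffer(raw[3:], dtype=np.uint8).reshape(p, bytes_per_snp)
    # unpack 2-bit genotype codes, sample-fastest within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(p, -1)[:, :n]
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    G = lut[codes].T  # samples x snps, counting A1
    snps = bim[["snp", "chr", "pos", "a1", "a2"]].copy()
    return _finalize_counts(G, snps, maf_min, on_missing)


def write_plink(genotypes: GenotypeMatrix, prefix) -> None:
    """Write counts (of a1) to a PLINK1 BED/BIM/FAM triplet."""
    prefix = Path(prefix)
    counts = genotypes.counts
    if counts is None:
        raise ValueError("genotype panel has no raw counts to write")
    n, p = counts.shape
    snps = genotypes.snps
    bim = pd.DataFrame(
        {
            "chr": snps.get("chr", 1),
            "snp": snps["snp"],
            "cm": 0,
            "pos": snps.get("pos", np.arange(1, p + 1)),
            "a1": snps["a1"],
            "a2": snps["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", index=False, header=False)
    fam = pd.DataFrame(
        {
            "fid": [f"F{i+1}" for i in range(n)],
            "iid": [f"I{i+1}" for i in range(n)],
            "pat": 0, "mat": 0, "sex": 0, "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", index=False, header=False)
    code_of = {2: 0b00, 1: 0b10, 0: 0b11}
    out = bytearray(_BED_MAGIC)
    for j in range(p):
        col = counts[:, j]
        byte = 0
        for i in range(n):
            c = col[i]
            code = 0b01 if np.isnan(float(c)) else code_of[int(c)]
            byte |= code << (2 * (i % 4))
            if i % 4 == 3:
                out.append(byte)
                byte = 0
        if n % 4:
            out.append(byte)
    prefix.with_suffix(".bed").write_bytes(bytes(out))


# ---------------------------------------------------------------------------
# summary statistics, LD, weights, expression
# ---------------------------------------------------------------------------


def read_sumstats(path) -> GwasSummary:
    df = _read_tsv(path)
    df.columns = [c.lower() for c in df.columns]
    _require_columns(df, ["snp", "a1", "a2", "z", "n"], path)
    bad = pd.to_numeric(df["z"], errors="coerce").isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}: non-numeric Z at line {line} (SNP {df.loc[bad.idxmax(), 'snp']!r})")
    df["z"] = df["z"].astype(float)
    return GwasSummary(table=df)


def write_sumstats(gwas: GwasSummary, path) -> None:
    cols = [c for c in _SUMSTAT_COLS if c in gwas.table.columns]
    gwas.table[cols].to_csv(path, sep="\t", index=False)


def read_ld(path) -> LDMatrix:
    """Square correlation-matrix TSV with SNP ids as the header row."""
    df = _read_tsv(path)
    return LDMatrix(snp_ids=list(df.columns), V=df.to_numpy(dtype=float))


def write_ld(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.V, columns=ld.snp_ids).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_weights(models: list[WeightModel], path) -> None:
    frames = [m.to_frame() for m in models]
    pd.concat(frames, ignore_index=True)[_WEIGHT_COLS].to_csv(path, sep="\t", index=False)


def read_weights(path) -> list[WeightModel]:
    df = _read_tsv(path)
    _require_columns(df, _WEIGHT_COLS, path)
    out = []
    for gene, g in df.groupby("gene", sort=True):
        pivot = g.pivot_table(index="snp", columns="isoform", values="weight", sort=False)
        iso_ids = list(pivot.columns)
        drop = [iso for iso in iso_ids if not np.isfinite(pivot[iso]).all()]
        for iso in drop:
            logger.warning("gene %s: isoform %s lacks weights for some SNPs; skipped", gene, iso)
        iso_ids = [i for i in iso_ids if i not in drop]
        if not iso_ids:
            logger.warning("gene %s: no usable isoform weight columns; skipped", gene)
            continue
        snp_meta = g.drop_duplicates("snp").set_index("snp").loc[pivot.index]
        snps = pd.DataFrame(
            {"snp": pivot.index, "a1": snp_meta["a1"].values, "a2": snp_meta["a2"].values}
        ).reset_index(drop=True)
        cv = g.drop_duplicates("isoform").set_index("isoform")["cv_r2"]
        out.append(
            WeightModel(
                gene=gene,
                isoform_ids=iso_ids,
                b_hat=pivot[iso_ids].to_numpy(dtype=float),
                snps=snps,
                cv_r2=cv.loc[iso_ids].to_numpy(dtype=float),
                method=str(g["method"].iloc[0]),
            )
        )
    if not out:
        raise ValueError(f"{path}: no usable weight models")
    return out


def write_expression(expression: np.ndarray, isoform_ids, path, iso2gene: dict | None = None, map_path=None) -> None:
    pd.DataFrame(expression, columns=list(isoform_ids)).to_csv(path, sep="\t", index=False)
    if iso2gene is not None and map_path is not None:
        pd.DataFrame(
            {"isoform": list(iso2gene), "gene": [iso2gene[k] for k in iso2gene]}
        ).to_csv(map_path, sep="\t", index=False)


def read_expression(path, map_path=None):
    df = _read_tsv(path)
    mapping = None
    if map_path is not None:
        mdf = _read_tsv(map_path)
        _require_columns(mdf, ["isoform", "gene"], map_path)
        mapping = dict(zip(mdf["isoform"], mdf["gene"]))
    return df, mapping


# ---------------------------------------------------------------------------
# config + manifest
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    with open(path, "rt", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def write_manifest(out_dir, config: dict, seed: int, outputs: list[str]) -> Path:
    """Record config hash, seed and package version for reproducibility."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
        "seed": seed,
        "version": __version__,
        "outputs": sorted(outputs),
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
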