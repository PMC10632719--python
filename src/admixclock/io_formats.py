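"""Tabular formats, configuration and logging shared by every pipeline stage.

All on-disk tables are TSV with optional ``#``-prefixed comment/header lines
and ``NA`` for missing values, matching the R-flavoured outputs (PLINK,
RFMix-like, REAP-like) the pipeline is designed to consume.  Genomic
coordinates are 1-based inclusive everywhere except BED exports, which are
0-based half-open.

Readers validate schema invariants up front and raise :class:`SchemaError`
with the offending column or cell coordinates; writers emit a canonical byte
layout so that ``write(read(x))`` is the identity on canonical files.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("admixclock")

VALID_ALLELES = frozenset("ACGT")
ANCESTRIES = ("AMR", "EUR", "AFR", "EAS")
UNKNOWN_ANCESTRY = "UNK"
NA_TOKEN = "NA"
_FLOAT_FMT = "%.10g"


class SchemaError(ValueError):
    """A table failed schema validation (missing column, bad cell, broken invariant)."""


def setup_logging(level: int = logging.INFO) -> logging.Logger:
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Run-wide settings: RNG seed, stage toggles and decision thresholds.

    Threshold defaults mirror the analysis conventions the pipeline implements:
    FDR q < 0.1 for the inter-population comparison, |Z| > 3 for the
    local-ancestry deviation scan, posterior > 0.9 for ancestry assignment and
    nominal p < 0.01 for the replication phase.
    """

    seed: int = 0
    out_dir: str = "admixclock_out"
    synthetic: bool = True
    stages: dict = field(default_factory=lambda: {
        "qc": True, "clocks": True, "compare": True, "scan": True,
        "replicate": True, "importance": True, "kinship": True,
    })
    # statistical thresholds
    fdr_q: float = 0.1
    inbreeding_fdr_q: float = 0.01
    shapiro_alpha: float = 0.05
    z_threshold: float = 3.0
    posterior_min: float = 0.9
    replication_alpha: float = 0.01
    # genotype QC thresholds
    mind: float = 0.05
    geno: float = 0.05
    hwe_p: float = 7.00e-08
    pihat_max: float = 0.25
    ld_window: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.2
    min_region_snps: int = 2
    # input paths (ignored in synthetic mode)
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        for name in ("fdr_q", "inbreeding_fdr_q", "shapiro_alpha", "posterior_min",
                     "replication_alpha", "mind", "geno", "hwe_p", "pihat_max",
                     "ld_r2_max"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

SAMPLE_REQUIRED = ("sample_id", "population", "age", "sex", "infected", "paraje")
POPULATIONS = ("groupA", "groupB")


@dataclass
class ClockDefinition:
    """A named linear DNAm estimator: intercept + sum(coef * beta), then a transform.

    ``kind`` distinguishes age clocks (output in years after the transform)
    from surrogate estimators (plasma-protein-like scores in clock units).
    ``transform`` is ``identity`` or ``horvath`` (piecewise log/linear age
    mapping with its ``adult_age`` knot).
    """

    name: str
    kind: str  # {age, surrogate}
    intercept: float
    coefficients: "pd.Series"  # index CpG id -> weight
    transform: str = "identity"  # {identity, horvath}
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in ("age", "surrogate"):
            raise SchemaError(f"clock kind must be age|surrogate, got {self.kind!r}")
        if self.transform not in ("identity", "horvath"):
            raise SchemaError(f"transform must be identity|horvath, got {self.transform!r}")
        if len(self.coefficients) < 1:
            raise SchemaError("clock needs at least one coefficient")
        if self.transform == "horvath" and self.adult_age <= 0:
            raise SchemaError("adult_age must be > 0 for horvath transform")


@dataclass
class GenotypeMatrix:
    """SNP records plus a sample x SNP dosage matrix of a1 counts (0/1/2/NaN)."""

    snps: pd.DataFrame      # columns: snp, chrom, pos, a1, a2 (pos 1-based)
    dosages: pd.DataFrame   # index: sample ids, columns: snp ids, float w/ NaN

    def __post_init__(self) -> None:
        need = {"snp", "chrom", "pos", "a1", "a2"}
        missing = need - set(self.snps.columns)
        if missing:
            raise SchemaError(f"genotype snp table missing columns: {sorted(missing)}")
        if list(self.dosages.columns) != list(self.snps["snp"]):
            raise SchemaError("dosage columns must match snp table order")
        for col in ("a1", "a2"):
            bad = ~self.snps[col].isin(list(VALID_ALLELES))
            if bad.any():
                raise SchemaError(f"invalid allele in column {col}: "
                                  f"{self.snps.loc[bad, col].iloc[0]!r}")
        for chrom, sub in self.snps.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise SchemaError(f"positions not strictly increasing on {chrom}")
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise SchemaError(
                f"dosage out of range at sample {self.dosages.index[i]!r}, "
                f"snp {self.dosages.columns[j]!r}: {vals[i, j]}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset(self, samples=None, snps=None) -> "GenotypeMatrix":
        dos = self.dosages
        snp_tab = self.snps
        if samples is not None:
            dos = dos.loc[list(samples)]
        if snps is not None:
            keep = [s for s in self.snps["snp"] if s in set(snps)]
            dos = dos[keep]
            snp_tab = snp_tab[snp_tab["snp"].isin(keep)].reset_index(drop=True)
        return GenotypeMatrix(snp_tab, dos)


@dataclass
class LocalAncestryCalls:
    """Hard per-haplotype ancestry labels along the genome.

    Haplotype columns are named ``<sample>_A`` / ``<sample>_B`` (two per
    sample); labels come from :data:`ANCESTRIES` plus ``UNK``.
    """

    snps: pd.DataFrame   # columns: chrom, pos, snp
    calls: pd.DataFrame  # index: snp id, columns: haplotype ids, values: labels

    def __post_init__(self) -> None:
        need = {"chrom", "pos", "snp"}
        missing = need - set(self.snps.columns)
        if missing:
            raise SchemaError(f"ancestry snp table missing columns: {sorted(missing)}")
        if list(self.calls.index) != list(self.snps["snp"]):
            raise SchemaError("call rows must match snp table order")
        valid = set(ANCESTRIES) | {UNKNOWN_ANCESTRY}
        labels = set(np.unique(self.calls.to_numpy()))
        if not labels <= valid:
            raise SchemaError(f"invalid ancestry labels: {sorted(labels - valid)}")
        for chrom, sub in self.snps.groupby("chrom", sort=False):
            if np.any(np.diff(sub["pos"].to_numpy()) <= 0):
                raise SchemaError(f"positions not strictly increasing on {chrom}")

    @property
    def haplotypes(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def samples(self) -> list[str]:
        seen: list[str] = []
        for h in self.calls.columns:
            s = h.rsplit("_", 1)[0]
            if s not in seen:
                seen.append(s)
        return seen


# ---------------------------------------------------------------------------
# Validation of DataFrame-backed tables
# ---------------------------------------------------------------------------

def validate_sample_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the metadata invariants; returns the validated frame."""
    for col in SAMPLE_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"sample table missing required column: {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"duplicate sample_id: {dup!r}")
    if len(df) and not np.isfinite(df["age"].to_numpy(dtype=float)).all():
        raise SchemaError("non-finite age")
    if len(df) and (df["age"].to_numpy(dtype=float) <= 0).any():
        raise SchemaError("ages must be > 0")
    bad_pop = ~df["population"].isin(POPULATIONS)
    if bad_pop.any():
        raise SchemaError(f"invalid population label: {df.loc[bad_pop, 'population'].iloc[0]!r}")
    if not df["sex"].isin(("F", "M")).all():
        raise SchemaError("sex must be F or M")
    for prefix in ("cell_", "anc_"):
        cols = [c for c in df.columns if c.startswith(prefix)]
        if cols:
            sums = df[cols].sum(axis=1, skipna=False).to_numpy(dtype=float)
            finite = np.isfinite(sums)
            if finite.any() and np.any(np.abs(sums[finite] - 1.0) > 1e-6):
                i = int(np.flatnonzero(finite & (np.abs(sums - 1.0) > 1e-6))[0])
                raise SchemaError(
                    f"{prefix}* columns must sum to 1 (sample {df['sample_id'].iloc[i]!r})")
    return df


def validate_beta_matrix(df: pd.DataFrame) -> pd.DataFrame:
    vals = df.to_numpy(dtype=float)
    ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise SchemaError(f"beta out of [0,1] at CpG {df.index[i]!r}, "
                          f"sample {df.columns[j]!r}: {vals[i, j]}")
    if df.index.duplicated().any():
        raise SchemaError("duplicate CpG ids in beta matrix")
    return df


# ---------------------------------------------------------------------------
# TSV primitives
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> tuple[dict, pd.DataFrame]:
    """Read TSV with '#'-comments; 'key=value' comments become header metadata."""
    meta: dict[str, str] = {}
    lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            lines.append(line)
    if not lines:
        raise SchemaError(f"{path}: no data rows")
    df = pd.read_csv(io.StringIO("".join(lines)), sep="\t", na_values=[NA_TOKEN],
                     keep_default_na=False, dtype=str)
    return meta, df


def _numeric(df: pd.DataFrame, cols, path, kind: str = "float") -> None:
    """Coerce columns to numeric in place; report row/column of a bad cell."""
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} at row {row}, column {col!r}")
        df[col] = coerced.astype(int) if kind == "int" else coerced


def _format_df(df: pd.DataFrame, float_cols=None) -> str:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: NA_TOKEN if pd.isna(v) else _FLOAT_FMT % v)
    return out.to_csv(sep="\t", index=False, na_rep=NA_TOKEN)


def _write_text(path: str | Path, text: str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        fh.write(text)


# ---------------------------------------------------------------------------
# Per-schema readers and writers
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path) -> pd.DataFrame:
    _, df = _read_tsv(path)
    for col in SAMPLE_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"{path}: sample table missing required column: {col!r}")
    num_cols = ["age"] + [c for c in df.columns
                          if c.startswith(("cell_", "anc_")) or c in ("inbreeding_f",)]
    _numeric(df, num_cols, path)
    for col in ("infected",):
        df[col] = df[col].map({"True": True, "False": False, "1": True, "0": False})
        if df[col].isna().any():
            raise SchemaError(f"{path}: column {col!r} must be boolean")
        df[col] = df[col].astype(bool)
    return validate_sample_table(df)


def write_sample_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_sample_table(df)
    out = df.copy()
    out["infected"] = out["infected"].map({True: "True", False: "False"})
    _write_text(path, _format_df(out))


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    _, df = _read_tsv(path)
    if "cpg" not in df.columns:
        raise SchemaError(f"{path}: beta matrix missing 'cpg' column")
    df = df.set_index("cpg")
    df = df.apply(pd.to_numeric, errors="raise")
    return validate_beta_matrix(df)


def write_beta_matrix(df: pd.DataFrame, path: str | Path) -> None:
    validate_beta_matrix(df)
    out = df.reset_index()
    out.columns = ["cpg"] + list(df.columns)
    _write_text(path, _format_df(out))


def read_clock(path: str | Path) -> ClockDefinition:
    meta, df = _read_tsv(path)
    for key in ("name", "kind", "intercept", "transform"):
        if key not in meta:
            raise SchemaError(f"{path}: clock header missing key {key!r}")
    for col in ("cpg", "coefficient"):
        if col not in df.columns:
            raise SchemaError(f"{path}: clock table missing column {col!r}")
    _numeric(df, ["coefficient"], path)
    coef = pd.Series(df["coefficient"].to_numpy(), index=df["cpg"].to_numpy(), name="coefficient")
    return ClockDefinition(
        name=meta["name"], kind=meta["kind"], intercept=float(meta["intercept"]),
        coefficients=coef, transform=meta["transform"],
        adult_age=float(meta.get("adult_age", 20.0)))


def write_clock(clock: ClockDefinition, path: str | Path) -> None:
    head = (f"# name={clock.name}\n# kind={clock.kind}\n"
            f"# intercept={_FLOAT_FMT % clock.intercept}\n"
            f"# transform={clock.transform}\n# adult_age={_FLOAT_FMT % clock.adult_age}\n")
    df = pd.DataFrame({"cpg": clock.coefficients.index,
                       "coefficient": clock.coefficients.to_numpy()})
    _write_text(path, head + _format_df(df))


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    _, df = _read_tsv(path)
    for col in ("snp", "chrom", "pos", "a1", "a2"):
        if col not in df.columns:
            raise SchemaError(f"{path}: genotype table missing column {col!r}")
    _numeric(df, ["pos"], path, kind="int")
    sample_cols = [c for c in df.columns if c not in ("snp", "chrom", "pos", "a1", "a2")]
    _numeric(df, sample_cols, path)
    snps = df[["snp", "chrom", "pos", "a1", "a2"]].reset_index(drop=True)
    dosages = df[sample_cols].T
    dosages.columns = snps["snp"]
    dosages.columns.name = None
    dosages.index.name = None
    return GenotypeMatrix(snps, dosages.astype(float))


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    df = g.snps.copy()
    body = g.dosages.T.reset_index(drop=True)
    for col in body.columns:
        df[col] = body[col].to_numpy()
    _write_text(path, _format_df(df))


def read_ancestry_calls(path: str | Path) -> LocalAncestryCalls:
    _, df = _read_tsv(path)
    for col in ("chrom", "pos", "snp"):
        if col not in df.columns:
            raise SchemaError(f"{path}: ancestry calls missing column {col!r}")
    _numeric(df, ["pos"], path, kind="int")
    hap_cols = [c for c in df.columns if c not in ("chrom", "pos", "snp")]
    snps = df[["chrom", "pos", "snp"]].reset_index(drop=True)
    calls = df[hap_cols].copy()
    calls.index = snps["snp"]
    calls.index.name = None
    return LocalAncestryCalls(snps, calls)


def write_ancestry_calls(calls: LocalAncestryCalls, path: str | Path) -> None:
    df = calls.snps.copy()
    for col in calls.calls.columns:
        df[col] = calls.calls[col].to_numpy()
    _write_text(path, _format_df(df))


def read_posteriors(path: str | Path) -> pd.DataFrame:
    """Long posterior table: chrom, pos, snp, haplotype, ancestry, posterior."""
    _, df = _read_tsv(path)
    need = ("chrom", "pos", "snp", "haplotype", "ancestry", "posterior")
    for col in need:
        if col not in df.columns:
            raise SchemaError(f"{path}: posterior table missing column {col!r}")
    _numeric(df, ["pos"], path, kind="int")
    _numeric(df, ["posterior"], path)
    return df


def write_posteriors(df: pd.DataFrame, path: str | Path) -> None:
    _write_text(path, _format_df(df))


def read_gwas_catalog(path: str | Path) -> pd.DataFrame:
    _, df = _read_tsv(path)
    need = ("snp", "chrom", "pos", "a1", "a2", "freq_a1", "effect_a1", "se", "p", "n")
    for col in need:
        if col not in df.columns:
            raise SchemaError(f"{path}: gwas catalog missing column {col!r}")
    _numeric(df, ["pos", "n"], path, kind="int")
    _numeric(df, ["freq_a1", "effect_a1", "se", "p"], path)
    if ((df["freq_a1"] <= 0) | (df["freq_a1"] >= 1)).any():
        raise SchemaError(f"{path}: freq_a1 must be in (0,1)")
    if (df["se"] <= 0).any():
        raise SchemaError(f"{path}: se must be > 0")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        raise SchemaError(f"{path}: p must be in (0,1]")
    return df


def write_gwas_catalog(df: pd.DataFrame, path: str | Path) -> None:
    _write_text(path, _format_df(df))


def read_kinship(path: str | Path) -> pd.DataFrame:
    _, df = _read_tsv(path)
    for col in ("id1", "id2", "pihat"):
        if col not in df.columns:
            raise SchemaError(f"{path}: kinship table missing column {col!r}")
    _numeric(df, ["pihat"], path)
    return df


def write_kinship(df: pd.DataFrame, path: str | Path) -> None:
    _write_text(path, _format_df(df))


def read_estimators(path: str | Path) -> pd.DataFrame:
    _, df = _read_tsv(path)
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path}: estimator table missing 'sample_id'")
    _numeric(df, [c for c in df.columns if c != "sample_id"], path)
    return df.set_index("sample_id")


def write_estimators(df: pd.DataFrame, path: str | Path) -> None:
    out = df.reset_index()
    out.columns = ["sample_id"] + list(df.columns)
    _write_text(path, _format_df(out))


def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Export called regions as BED (0-based half-open)."""
    bed = pd.DataFrame({
        "chrom": regions["chrom"],
        "start": regions["start"].astype(int) - 1,
        "end": regions["end"].astype(int),
        "name": [f"region_{i}" for i in range(len(regions))],
    })
    _write_text(path, bed.to_csv(sep="\t", index=False, header=False))


_READERS = {
    "samples": read_sample_table,
    "betas": read_beta_matrix,
    "clock": read_clock,
    "genotypes": read_genotypes,
    "ancestry_calls": read_ancestry_calls,
    "posteriors": read_posteriors,
    "gwas_catalog": read_gwas_catalog,
    "kinship": read_kinship,
    "estimators": read_estimators,
}

_WRITERS = {
    "samples": write_sample_table,
    "betas": write_beta_matrix,
    "clock": write_clock,
    "genotypes": write_genotypes,
    "ancestry_calls": write_ancestry_calls,
    "posteriors": write_posteriors,
    "gwas_catalog": write_gwas_catalog,
    "kinship": write_kinship,
    "estimators": write_estimators,
}


def read_table(path: str | Path, schema: str):
    """Read any pipeline table by schema kind; see module docstring for kinds."""
    if schema not in _READERS:
        raise SchemaError(f"unknown schema kind {schema!r}; known: {sorted(_READERS)}")
    if not Path(path).exists():
        raise FileNotFoundError(path)
    return _READERS[schema](path)


def write_table(obj, path: str | Path, schema: str) -> None:
    if schema not in _WRITERS:
        raise SchemaError(f"unknown schema kind {schema!r}; known: {sorted(_WRITERS)}")
    _WRITERS[schema](obj, path)
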