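"""Core data model, delimited-table readers/writers, and beta/M transforms.

The universal substrate is a :class:`BetaCohort`: a probes x samples matrix of
methylation beta values (fraction methylated, in [0, 1]) together with a probe
manifest (genomic coordinates) and a sample sheet (phenotype / batch metadata).
All downstream stages (QC, outlier-DMR scanning, episignature derivation,
DMR calling) operate on this container or on slices of it.

Coordinate conventions
----------------------
Manifest positions are 1-based (Illumina convention).  All interval arithmetic
and every exported BED/bedGraph record use 0-based half-open coordinates; the
conversion happens exactly once, at export (``pos - 1`` for the start).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BetaCohort",
    "ParseError",
    "ValidationError",
    "beta_to_m",
    "m_to_beta",
    "read_cohort",
    "read_table",
    "write_cohort",
    "export_tracks",
    "CHROM_CLASS_AUTOSOME",
    "CHROM_CLASS_X",
    "CHROM_CLASS_Y",
    "classify_chrom",
]

CHROM_CLASS_AUTOSOME = "autosome"
CHROM_CLASS_X = "X"
CHROM_CLASS_Y = "Y"

DEFAULT_LOGIT_EPS = 1e-6


class ParseError(ValueError):
    """Raised when an input table cannot be parsed."""


class ValidationError(ValueError):
    """Raised when parsed inputs violate a data-model invariant."""


def classify_chrom(chrom: str) -> str:
    """Classify a chromosome name as autosome / X / Y.

    Accepts both ``chrX`` and bare ``X`` style names.
    """
    name = str(chrom)
    if name.lower().startswith("chr"):
        name = name[3:]
    if name.upper() == "X":
        return CHROM_CLASS_X
    if name.upper() == "Y":
        return CHROM_CLASS_Y
    return CHROM_CLASS_AUTOSOME


@dataclass
class BetaCohort:
    """Probes x samples beta matrix with aligned manifest and sample sheet.

    Attributes
    ----------
    beta
        DataFrame indexed by probe_id, columns sample ids, float values in
        [0, 1]; NaN marks missing measurements.
    manifest
        DataFrame indexed by probe_id with at least columns ``chrom`` (str),
        ``pos`` (1-based int) and ``chrom_class``; optional annotation columns
        (``gene``, ``cgi_relation``) are carried through untouched.
    samples
        DataFrame indexed by sample_id with at least columns ``reported_sex``
        (male / female / unknown), ``batch``, ``group``; optional ``age`` and
        ``replicate_of``.
    detection_p
        Optional DataFrame of detection p-values, same shape as ``beta``.
    inferred_sex
        Optional Series (sample_id -> male/female), filled by QC.
    """

    beta: pd.DataFrame
    manifest: pd.DataFrame
    samples: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    inferred_sex: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        if not self.beta.index.is_unique:
            dup = self.beta.index[self.beta.index.duplicated()][0]
            raise ValidationError(f"duplicate probe_id in beta matrix: {dup!r}")
        if not self.samples.index.is_unique:
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise ValidationError(f"duplicate sample_id in sheet: {dup!r}")
        missing = self.beta.index.difference(self.manifest.index)
        if len(missing):
            raise ValidationError(
                f"probe(s) in beta matrix absent from manifest: {list(missing[:5])}"
            )
        sheet_missing = self.beta.columns.difference(self.samples.index)
        if len(sheet_missing):
            raise ValidationError(
                f"sample(s) in beta matrix absent from sheet: {list(sheet_missing[:5])}"
            )
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            bad = np.argwhere((vals < 0.0) | (vals > 1.0))
            r, c = bad[0]
            raise ValidationError(
                "beta value outside [0, 1]: "
                f"probe={self.beta.index[r]!r} sample={self.beta.columns[c]!r} "
                f"value={vals[r, c]!r}"
            )
        if self.detection_p is not None and self.detection_p.shape != self.beta.shape:
            raise ValidationError(
                f"detection_p shape {self.detection_p.shape} != beta shape {self.beta.shape}"
            )
        if (self.manifest.loc[self.beta.index, "pos"] < 1).any():
            raise ValidationError("manifest positions must be >= 1 (1-based)")

    # -- convenience -----------------------------------------------------

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def probe_manifest(self) -> pd.DataFrame:
        """Manifest rows restricted and ordered to the beta matrix."""
        return self.manifest.loc[self.beta.index]

    def subset_probes(self, probe_ids) -> "BetaCohort":
        """Return a cohort restricted to ``probe_ids`` (order preserved)."""
        idx = self.beta.index.intersection(pd.Index(probe_ids), sort=False)
        keep = self.beta.index[self.beta.index.isin(idx)]
        return self._replace(
            beta=self.beta.loc[keep],
            detection_p=None if self.detection_p is None else self.detection_p.loc[keep],
        )

    def drop_probes(self, probe_ids) -> "BetaCohort":
        keep = self.beta.index[~self.beta.index.isin(set(probe_ids))]
        return self._replace(
            beta=self.beta.loc[keep],
            detection_p=None if self.detection_p is None else self.detection_p.loc[keep],
        )

    def subset_samples(self, sample_ids) -> "BetaCohort":
        keep = [s for s in self.beta.columns if s in set(sample_ids)]
        return self._replace(
            beta=self.beta[keep],
            detection_p=None if self.detection_p is None else self.detection_p[keep],
            samples=self.samples.loc[keep],
            inferred_sex=None if self.inferred_sex is None else self.inferred_sex.reindex(keep),
        )

    def sorted_by_position(self) -> "BetaCohort":
        """Return a cohort with probes sorted by (chrom, pos)."""
        man = self.probe_manifest()
        order = man.sort_values(["chrom", "pos"], kind="mergesort").index
        return self._replace(
            beta=self.beta.loc[order],
            detection_p=None if self.detection_p is None else self.detection_p.loc[order],
        )

    def _replace(self, **kw) -> "BetaCohort":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# beta / M transforms
# ---------------------------------------------------------------------------

def beta_to_m(beta, eps: float = DEFAULT_LOGIT_EPS):
    """Logit-transform beta values to M-values: M = log2(beta / (1 - beta)).

    Values are clipped to [eps, 1 - eps] first so that boundary betas map to
    large finite M-values instead of infinities.  Accepts scalars or arrays
    (NaN passes through as NaN).

    Raises
    ------
    ValidationError
        If any finite input lies outside [0, 1].
    """
    arr = np.asarray(beta, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise ValidationError("beta values must lie in [0, 1]")
    clipped = np.clip(arr, eps, 1.0 - eps)
    m = np.log2(clipped / (1.0 - clipped))
    if np.isscalar(beta) or np.ndim(beta) == 0:
        return float(m)
    return m


def m_to_beta(m):
    """Inverse logit: beta = 2**M / (2**M + 1).  Exact inverse on (0, 1)."""
    arr = np.asarray(m, dtype=float)
    # logistic in base 2, computed stably for large |M|
    beta = np.where(arr >= 0, 1.0 / (1.0 + np.exp2(-arr)),
                    np.exp2(arr) / (1.0 + np.exp2(arr)))
    if np.isscalar(m) or np.ndim(m) == 0:
        return float(beta)
    return beta


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_table(path: str | os.PathLike, index_col: int = 0) -> pd.DataFrame:
    """Read a TSV/CSV table, sniffing the delimiter from the extension.

    ``.csv`` is comma-separated; everything else is tab-separated.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    try:
        return pd.read_csv(path, sep=sep, index_col=index_col)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ParseError(f"malformed table {path}: {exc}") from exc


def read_cohort(
    beta_path: str | os.PathLike,
    manifest_path: str | os.PathLike,
    sheet_path: str | os.PathLike,
    detection_p_path: str | os.PathLike | None = None,
) -> BetaCohort:
    """Load a cohort from delimited tables and validate alignment.

    The beta table has probe ids in the first column and one column per
    sample; the manifest has columns ``probe_id, chrom, pos`` (plus optional
    annotations); the sheet has ``sample_id, reported_sex, batch, group`` and
    optional ``age``, ``replicate_of``.
    """
    beta = read_table(beta_path).astype(float)
    manifest = read_table(manifest_path)
    sheet = read_table(sheet_path)
    if "chrom_class" not in manifest.columns:
        manifest = manifest.assign(chrom_class=[classify_chrom(c) for c in manifest["chrom"]])
    detection_p = None
    if detection_p_path is not None:
        detection_p = read_table(detection_p_path).astype(float)
        detection_p = detection_p.loc[beta.index, beta.columns]
    return BetaCohort(beta=beta, manifest=manifest, samples=sheet, detection_p=detection_p)


def write_cohort(cohort: BetaCohort, out_dir: str | os.PathLike, prefix: str = "cohort") -> dict:
    """Write beta / manifest / sheet (and detection p) as TSVs; return paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "beta": os.path.join(out_dir, f"{prefix}.beta.tsv"),
        "manifest": os.path.join(out_dir, f"{prefix}.manifest.tsv"),
        "sheet": os.path.join(out_dir, f"{prefix}.samples.tsv"),
    }
    cohort.beta.to_csv(paths["beta"], sep="\t", index_label="probe_id")
    cohort.probe_manifest().to_csv(paths["manifest"], sep="\t", index_label="probe_id")
    cohort.samples.to_csv(paths["sheet"], sep="\t", index_label="sample_id")
    if cohort.detection_p is not None:
        paths["detection_p"] = os.path.join(out_dir, f"{prefix}.detp.tsv")
        cohort.detection_p.to_csv(paths["detection_p"], sep="\t", index_label="probe_id")
    return paths


# ---------------------------------------------------------------------------
# Track export
# ---------------------------------------------------------------------------

def export_tracks(
    cohort: BetaCohort,
    regions,
    out_dir: str | os.PathLike,
    bed_name: str = "regions.bed",
) -> dict:
    """Export region BED plus one bedGraph of beta values per sample.

    ``regions`` is an iterable of (chrom, start_1based, end_1based_inclusive,
    name) or (chrom, start, end) tuples, in manifest coordinates; the BED is
    written 0-based half-open.  Each sample's bedGraph holds one 1-bp interval
    per probe with a non-missing beta; chromosomes where a sample has no
    observed beta are simply absent from that sample's file.

    Raises
    ------
    ValidationError
        If a region names a chromosome absent from the manifest.
    """
    os.makedirs(out_dir, exist_ok=True)
    known_chroms = set(cohort.probe_manifest()["chrom"].astype(str))
    bed_path = os.path.join(out_dir, bed_name)
    with open(bed_path, "w") as fh:
        fh.write('track name="regions"\n')
        for i, region in enumerate(regions):
            chrom, start, end = region[0], int(region[1]), int(region[2])
            name = region[3] if len(region) > 3 else f"region_{i + 1}"
            if str(chrom) not in known_chroms:
                raise ValidationError(f"unknown chromosome in region: {chrom!r}")
            bed_start = start - 1  # 1-based inclusive -> 0-based half-open
            if bed_start >= end:
                raise ValidationError(f"empty interval after conversion: {region!r}")
            fh.write(f"{chrom}\t{bed_start}\t{end}\t{name}\n")

    paths = {"bed": bed_path}
    man = cohort.probe_manifest()
    for sample in cohort.beta.columns:
        values = cohort.beta[sample]
        keep = values.notna()
        path = os.path.join(out_dir, f"{sample}.beta.bedGraph")
        sub = man.loc[keep[keep].index].assign(beta=values[keep])
        sub = sub.sort_values(["chrom", "pos"], kind="mergesort")
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="{sample} beta"\n')
            for chrom, pos, b in zip(sub["chrom"], sub["pos"], sub["beta"]):
                fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{b:.6g}\n")
        paths[sample] = path
    return paths
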