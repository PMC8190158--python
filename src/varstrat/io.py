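"""TSV and VCF plumbing for the variance-stratification workflow.

TSV dialect throughout: tab-delimited, mandatory header, '.' for missing,
UTF-8. Variant identifiers from VCF records are ``chrom:pos:ref:alt``
(1-based positions, per the VCF standard); the coded allele is ALT
everywhere, which is safe because lambda_vs is invariant to a global
allele flip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from varstrat.inflation import GroupSummary
from varstrat.models import AssocResult, CohortTable

__all__ = [
    "read_group_summaries",
    "read_freqs",
    "read_sample_map",
    "read_cohort",
    "write_lambda_table",
    "write_assoc_results",
    "group_freqs_from_vcf",
    "RunConfig",
]

logger = logging.getLogger(__name__)

MISSING = "."


def _read_tsv(path: Union[str, Path], required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING], dtype={"group_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_group_summaries(path: Union[str, Path]) -> list[GroupSummary]:
    """Read the per-group roster TSV (columns group_id, n, sigma2).

    Malformed rows are reported with their 1-based data line number;
    duplicate group ids are rejected.
    """
    df = _read_tsv(path, ["group_id", "n", "sigma2"])
    groups: list[GroupSummary] = []
    seen: set[str] = set()
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            g = GroupSummary(
                group_id=str(row.group_id),
                n=int(row.n),
                p=0.5,  # placeholder; per-variant frequencies come separately
                sigma2=float(row.sigma2),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} line {line_no}: {exc}") from exc
        if g.group_id in seen:
            raise ValueError(f"{path} line {line_no}: duplicate group_id {g.group_id!r}")
        seen.add(g.group_id)
        groups.append(g)
    if not groups:
        raise ValueError(f"{path}: no groups found")
    return groups


def read_freqs(path: Union[str, Path], groups: Sequence[GroupSummary]) -> pd.DataFrame:
    """Read the per-variant frequency TSV: variant_id + one column per group."""
    df = _read_tsv(path, ["variant_id"])
    missing = [g.group_id for g in groups if g.group_id not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing frequency columns for groups {missing}")
    return df


def read_sample_map(path: Union[str, Path]) -> pd.DataFrame:
    """Read the sample-to-analysis-group map (columns sample_id, group_id)."""
    df = _read_tsv(path, ["sample_id", "group_id"])
    df["sample_id"] = df["sample_id"].astype(str)
    dup = df["sample_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: samples mapped more than once: {sorted(df['sample_id'][dup])}"
        )
    if df["group_id"].isna().any():
        raise ValueError(f"{path}: missing group_id entries")
    return df


def read_cohort(
    path: Union[str, Path], dosage_cols: Sequence[str] = ()
) -> CohortTable:
    """Read a per-sample cohort TSV into a CohortTable."""
    df = _read_tsv(path, ["sample_id", "group_id", "y"])
    return CohortTable(df, dosage_cols=tuple(dosage_cols))


def write_lambda_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write the variant_id / lambda_vs / category TSV."""
    table.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def write_assoc_results(
    results: Sequence[AssocResult], path: Union[str, Path]
) -> None:
    """Write per-variant association results (one row per variant/model)."""
    df = pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "model": r.model,
                "beta": r.beta,
                "se": r.se,
                "chi2": r.chi2,
                "p": r.p,
            }
            for r in results
        ]
    )
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def _record_dosages(variant, n_samples: int) -> np.ndarray:
    """ALT-dosage vector for one VCF record: DS field if present, else GT.

    Half-calls and missing genotypes give NaN.
    """
    try:
        ds = variant.format("DS")
    except KeyError:
        ds = None
    if ds is not None:
        return np.asarray(ds, dtype=float).reshape(n_samples)
    geno = np.asarray([gt[:2] for gt in variant.genotypes], dtype=int)
    out = geno.sum(axis=1).astype(float)
    out[(geno < 0).any(axis=1)] = np.nan  # half-calls count as missing
    return out


def group_freqs_from_vcf(
    vcf_path: Union[str, Path],
    sample_map: pd.DataFrame,
    min_mac: int = 20,
) -> pd.DataFrame:
    """Per-group ALT-allele frequencies for biallelic variants in a VCF.

    Multi-allelic records are skipped (and counted in the log); variants
    with pooled minor allele count below ``min_mac`` are excluded.
    Missing genotypes leave the per-group denominator; a group with no
    called genotypes at a site gets a missing frequency and the variant
    is flagged in the ``incomplete`` column.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    mapped = sample_map["sample_id"].tolist()
    absent = [s for s in mapped if s not in vcf_samples]
    if absent:
        raise ValueError(f"samples in map but absent from VCF: {absent}")

    sample_idx = np.array([vcf_samples.index(s) for s in mapped])
    group_ids = sample_map["group_id"].tolist()
    group_names = list(pd.unique(sample_map["group_id"]))
    group_masks = {
        gid: np.array([g == gid for g in group_ids]) for gid in group_names
    }

    rows = []
    n_multi = 0
    n_low_mac = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        dosage = _record_dosages(variant, len(vcf_samples))[sample_idx]
        called = np.isfinite(dosage)
        alt_alleles = np.nansum(dosage)
        total_alleles = 2.0 * called.sum()
        if total_alleles == 0:
            continue
        mac = min(alt_alleles, total_alleles - alt_alleles)
        if mac < min_mac:
            n_low_mac += 1
            continue
        vid = f"{variant.CHROM}:{variant.POS}:{variant.REF}:{variant.ALT[0]}"
        row: dict[str, object] = {"variant_id": vid}
        incomplete = False
        for gid in group_names:
            m = group_masks[gid] & called
            denom = 2.0 * m.sum()
            if denom == 0:
                row[gid] = np.nan
                incomplete = True
            else:
                row[gid] = float(dosage[m].sum() / denom)
        row["incomplete"] = incomplete
        rows.append(row)
    if n_multi:
        logger.info("skipped %d multi-allelic records", n_multi)
    if n_low_mac:
        logger.info("excluded %d variants with pooled MAC < %d", n_low_mac, min_mac)
    return pd.DataFrame(rows, columns=["variant_id", *group_names, "incomplete"])


@dataclass
class RunConfig:
    """Structured configuration for simulation runs.

    ``settings`` selects grid cells: "all", or a list of 0-based indices
    into the deterministic grid enumeration.
    """

    n_reps: int = 10000
    seed: int = 0
    settings: Union[str, list[int]] = "all"
    out: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_reps < 100:
            raise ValueError("n_reps must be >= 100")
        if isinstance(self.settings, str) and self.settings != "all":
            raise ValueError("settings must be 'all' or a list of grid indices")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)
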