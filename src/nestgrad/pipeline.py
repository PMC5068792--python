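"""Pipeline orchestration: pool -> normalize -> sort -> test -> report.

`analyze_table` is the library entry point running the whole analysis on a
sample table in memory; `run_pipeline` adds file I/O, config validation, and
a JSON report with full provenance (seeds, package version, config echo) so
every reported p-value and Z-score is replayable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

import nestgrad
from nestgrad.data import (
    SampleTable,
    normalize_relative_abundance,
    pool_to_matrix,
    read_sample_table,
    sort_columns_by_gradient,
    sort_rows_by_occurrence,
    to_presence_absence,
    write_matrix,
)
from nestgrad.diversity import generality_correlation, generality_profiles, sufficiency_check
from nestgrad.multivariate import DistanceMatrix, mantel, pairwise_distances, permanova_oneway
from nestgrad.nestedness import nestedness_test, sample_weighted_null
from nestgrad.sdr import sdr_simplex

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_RUNTIME = 3


@dataclass
class PipelineConfig:
    samples_path: str
    out_dir: str = "nestgrad_out"
    n_null: int = 1000
    n_perm: int = 9999
    seed: int = 0
    min_occurrences: int = 3
    descending_gradient: bool = True
    sufficiency_threshold: float = 0.4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        errors = validate_config_dict(raw)
        if errors:
            raise ValueError("invalid pipeline config:\n  " + "\n  ".join(errors))
        return cls(**raw)


def validate_config_dict(raw: dict) -> list[str]:
    """Collect *all* violations instead of stopping at the first."""
    errors: list[str] = []
    if not isinstance(raw, dict):
        return ["config must be a mapping"]
    known = set(PipelineConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            errors.append(f"unknown field {key!r}")
    if "samples_path" not in raw:
        errors.append("missing required field 'samples_path'")
    elif not Path(raw["samples_path"]).exists():
        errors.append(f"samples_path does not exist: {raw['samples_path']!r}")
    for key in ("n_null", "n_perm"):
        if key in raw and (not isinstance(raw[key], int) or raw[key] < 0):
            errors.append(f"{key} must be a non-negative integer")
    if "min_occurrences" in raw and (
        not isinstance(raw["min_occurrences"], int) or raw["min_occurrences"] < 1
    ):
        errors.append("min_occurrences must be a positive integer")
    if "sufficiency_threshold" in raw and raw["sufficiency_threshold"] <= 0:
        errors.append("sufficiency_threshold must be positive")
    return errors


def validate_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_yaml(path)


def analyze_table(
    table: SampleTable,
    n_null: int = 1000,
    n_perm: int = 9999,
    seed: int | None = None,
    min_occurrences: int = 3,
    descending_gradient: bool = True,
    sufficiency_threshold: float = 0.4,
) -> dict:
    """Full in-memory analysis of a sample table.

    Returns a dict with the sorted matrices, nestedness tests (NODF over
    columns on presence/absence, WNODF over rows on relative abundance), SDR
    decompositions in both modes, pH-generality correlation, rarefaction
    sufficiency per group, and (when ``n_perm`` > 0) one-way PERMANOVA of
    site on sample-level Jaccard distances and a Mantel test of Morisita-Horn
    site dissimilarity against pH distance.
    """
    ss = np.random.SeedSequence(seed)
    sub = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)]

    counts = pool_to_matrix(table)
    counts = sort_rows_by_occurrence(
        sort_columns_by_gradient(counts, descending=descending_gradient)
    )
    sizes = {g: meta.n_samples for g, meta in table.groups.items()}
    rel = normalize_relative_abundance(counts, sizes)
    pres = to_presence_absence(rel)
    logger.info("pooled matrix: %d phylotypes x %d groups", *rel.shape)

    out: dict = {"matrix_presence": pres, "matrix_abundance": rel, "matrix_counts": counts}
    out["nodf_columns"] = nestedness_test(
        pres, metric="nodf", axis="columns", n_null=n_null, seed=sub[0]
    )
    # WNODF null: margins-fixed randomization of the occurrence counts pushed
    # through the same per-column normalization as the observed matrix
    col_n = np.array([sizes[g] for g in counts.col_labels], dtype=float)
    wnodf_nulls = (
        100.0 * a / col_n[np.newaxis, :]
        for a in sample_weighted_null(counts.cells, n_null, seed=sub[1], scheme="margins_fixed")
    )
    out["wnodf_rows"] = nestedness_test(
        rel, metric="wnodf", axis="rows", n_null=n_null, seed=sub[1],
        nulls=wnodf_nulls, sampler_label="weighted/margins_fixed+normalize",
    )
    out["sdr_binary"] = sdr_simplex(pres, mode="binary")
    out["sdr_abundance"] = sdr_simplex(rel, mode="abundance")
    out["generality"] = generality_correlation(
        generality_profiles(table, min_occurrences=min_occurrences)
    )

    clone_totals: dict[str, int] = {}
    for rec in table.records:
        clone_totals.setdefault(rec.group_id, 0)
        clone_totals[rec.group_id] += rec.clone_count
    suff = {}
    for gid in rel.col_labels:
        g_counts: dict[str, int] = {}
        for rec in table.records:
            if rec.group_id == gid:
                g_counts[rec.phylotype_id] = g_counts.get(rec.phylotype_id, 0) + rec.clone_count
        if sum(g_counts.values()) >= 2:
            suff[gid] = sufficiency_check(
                list(g_counts.values()), threshold=sufficiency_threshold
            )
    out["sufficiency"] = suff

    if n_perm > 0:
        # sample-level presence/absence matrix for PERMANOVA
        sample_ids = table.sample_ids
        phylos = table.phylotype_ids
        p_idx = {p: i for i, p in enumerate(phylos)}
        s_idx = {s: i for i, s in enumerate(sample_ids)}
        samp = np.zeros((len(sample_ids), len(phylos)))
        site_of: dict[str, str] = {}
        for rec in table.records:
            samp[s_idx[rec.sample_id], p_idx[rec.phylotype_id]] = 1.0
            site_of[rec.sample_id] = rec.group_id
        d_jac = pairwise_distances(samp, metric="jaccard", axis="rows", labels=sample_ids)
        out["permanova"] = permanova_oneway(
            d_jac, [site_of[s] for s in sample_ids], n_perm=n_perm, seed=sub[2]
        )
        d_mh = pairwise_distances(counts, metric="morisita-horn", axis="columns")
        ph = np.array([table.groups[g].mean_ph for g in counts.col_labels], dtype=float)
        d_ph = DistanceMatrix(
            labels=list(counts.col_labels), values=np.abs(ph[:, None] - ph[None, :])
        )
        out["mantel"] = mantel(d_mh, d_ph, n_perm=n_perm, seed=sub[3])
    return out


def _result_to_json(out: dict) -> dict:
    rpt: dict = {}
    for key in ("nodf_columns", "wnodf_rows"):
        rpt[key] = out[key].to_dict()
    for key in ("sdr_binary", "sdr_abundance"):
        r = out[key]
        rpt[key] = {
            "pct_turnover": r.pct_turnover,
            "pct_agreement": r.pct_agreement,
            "pct_nestedness": r.pct_nestedness,
            "mode": r.mode,
            "aggregate": r.aggregate,
        }
    r, p, n = out["generality"]
    rpt["generality"] = {"r": r, "p": p, "n": n}
    rpt["sufficiency"] = {
        g: {"passed": bool(ok), "ci95_halfwidth": hw} for g, (ok, hw) in out["sufficiency"].items()
    }
    if "permanova" in out:
        t = out["permanova"].term("groups")
        rpt["permanova"] = {"df": t.df, "pseudo_f": t.pseudo_f, "p": t.p}
    if "mantel" in out:
        rpt["mantel"] = {"r": out["mantel"].r, "p": out["mantel"].p}
    return rpt


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured analysis end to end, writing a JSON report plus
    per-stage TSVs to the output directory.  Deterministic given the seed
    (the report's timestamp field aside)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = read_sample_table(config.samples_path)
    out = analyze_table(
        table,
        n_null=config.n_null,
        n_perm=config.n_perm,
        seed=config.seed,
        min_occurrences=config.min_occurrences,
        descending_gradient=config.descending_gradient,
        sufficiency_threshold=config.sufficiency_threshold,
    )
    write_matrix(out["matrix_presence"], out_dir / "matrix_presence.tsv")
    write_matrix(out["matrix_abundance"], out_dir / "matrix_abundance.tsv")
    out["sdr_binary"].pairs.to_csv(out_dir / "sdr_binary_pairs.tsv", sep="\t", index=False)
    out["sdr_abundance"].pairs.to_csv(out_dir / "sdr_abundance_pairs.tsv", sep="\t", index=False)

    report = {
        "provenance": {
            "package": "nestgrad",
            "version": nestgrad.__version__,
            "config": asdict(config),
            "seed": config.seed,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
        "results": _result_to_json(out),
    }
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
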