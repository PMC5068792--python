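"""Synthetic community generator for gradient-nestedness analyses.

Emulates the sampling design of a multi-site soil survey: sites spanning a
soil-pH gradient, a dozen rhizosphere samples per site with small within-site
pH scatter, and ~50 phylotypes whose occurrence is governed by a lower pH
tolerance limit L_j.  Under the ``nested`` regime a phylotype can occur in
any sample whose pH is at or above its limit (so acid-tolerant phylotypes,
with low L_j, span the whole gradient: the generalist continuum), occupancy
being Bernoulli-thinned so pooled frequencies vary; under ``turnover``
occupancy is confined to a window [L_j, L_j + w]; under ``random`` occupancy
ignores pH entirely.  A site-level availability layer (each phylotype's
propagules reach a given site with probability ``site_availability_prob``,
independent of pH) adds the patchiness real surveys show from dispersal
limitation and soil type, so pooled presence matrices are strongly but not
perfectly nested.

Clone counts per sample are multinomial over the phylotypes present.  With
``dominance_shift`` on, multinomial weights are Gaussian in pH around a
per-phylotype abundance optimum placed just above its tolerance limit, so
dominants change along the gradient: incidence stays nested while abundance
is anti-nested, the signature the analysis pipeline is designed to detect.

Detection is clone-limited by default: a phylotype colonizing a sample enters
the record only if it draws at least one of the sample's clones, just as a
real clone library misses rare community members.  This is the channel by
which abundance structure reaches the pooled frequency matrix (pooling counts
samples-with-detection, not clones) and it keeps pooled presence matrices
imperfectly nested, as in real surveys.  ``detection="complete"`` instead
guarantees every colonist at least one clone, making occupancy and detection
coincide (useful for exactness checks: with full occupancy the pooled
presence matrix is then perfectly nested by construction).

The generator always returns the ground truth (limits, optima, sample pH)
alongside the data, and is byte-deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from nestgrad.data import SampleRecord, SampleTable
from nestgrad.diversity import generality_profiles


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic survey.

    Defaults mirror a six-site gradient spanning strongly acidic to neutral
    soil (means 3.2-7.2), 12 samples per site, and 50 phylotypes with lower
    tolerance limits uniform on [3.0, 7.0].
    """

    n_sites: int = 6
    site_mean_ph: Sequence[float] | None = None  # default: linspace 3.2..7.2
    samples_per_site: int = 12
    sample_ph_sd: float = 0.2
    n_phylotypes: int = 50
    tolerance_ph_lo: float = 3.0
    tolerance_ph_hi: float = 7.0
    regime: str = "nested"  # nested | turnover | random
    occupancy_prob: float = 0.6
    occupancy_ramp: float = 0.0  # pH units; >0 thins occupancy toward the niche edge
    site_availability_prob: float = 0.6  # site-level propagule availability
    niche_width: float = 1.5  # pH units, turnover regime window
    clones_per_sample: int = 25
    dominance_shift: bool = False
    dominance_offset: float = 0.25  # optimum = L_j + offset
    dominance_width: float = 0.5  # Gaussian width of the abundance optimum
    dominance_floor: float = 0.3  # baseline clone weight far from the optimum
    detection: str = "clone_limited"  # clone_limited | complete
    seed: int | None = None

    def resolved_site_ph(self) -> np.ndarray:
        if self.site_mean_ph is None:
            return np.linspace(3.2, 7.2, self.n_sites)
        ph = np.asarray(self.site_mean_ph, dtype=float)
        if len(ph) != self.n_sites:
            raise ValueError("site_mean_ph length must equal n_sites")
        return ph

    def validate(self) -> None:
        if not 0.0 <= self.occupancy_prob <= 1.0:
            raise ValueError("occupancy_prob must be in [0, 1]")
        if not 0.0 <= self.site_availability_prob <= 1.0:
            raise ValueError("site_availability_prob must be in [0, 1]")
        ph = self.resolved_site_ph()
        if not (np.diff(ph) > 0).all():
            raise ValueError("site_mean_ph must be strictly increasing")
        if self.regime not in ("nested", "turnover", "random"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.tolerance_ph_hi < self.tolerance_ph_lo:
            raise ValueError("tolerance limits out of order")
        if self.samples_per_site < 1 or self.n_phylotypes < 1:
            raise ValueError("samples_per_site and n_phylotypes must be >= 1")
        if self.clones_per_sample < 1:
            raise ValueError("clones_per_sample must be >= 1")
        if self.sample_ph_sd < 0 or self.niche_width <= 0 or self.dominance_width <= 0:
            raise ValueError("scales must be positive")
        if self.dominance_floor < 0:
            raise ValueError("dominance_floor must be non-negative")
        if self.detection not in ("clone_limited", "complete"):
            raise ValueError(f"unknown detection mode {self.detection!r}")


@dataclass
class SimulationTruth:
    """Ground truth emitted next to every simulated dataset."""

    phylotypes: pd.DataFrame  # phylotype, lower_limit, upper_limit, abundance_optimum
    samples: pd.DataFrame  # sample_id, site, ph


def simulate(config: SimulationConfig) -> tuple[SampleTable, SimulationTruth]:
    """Generate one synthetic survey dataset plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    site_ph = config.resolved_site_ph()
    site_ids = [f"site{k + 1:02d}" for k in range(config.n_sites)]

    sample_rows = []
    for k, sid in enumerate(site_ids):
        for s in range(config.samples_per_site):
            ph = float(np.clip(rng.normal(site_ph[k], config.sample_ph_sd), 0.0, 14.0))
            sample_rows.append({"sample_id": f"{sid}_s{s + 1:02d}", "site": sid, "ph": ph})
    samples = pd.DataFrame(sample_rows)
    max_ph = float(samples["ph"].max())

    limits = rng.uniform(config.tolerance_ph_lo, config.tolerance_ph_hi, config.n_phylotypes)
    limits.sort()  # phylo01 = most acid-tolerant; cosmetic, rng order is immaterial
    phylo_ids = [f"phylo{j + 1:02d}" for j in range(config.n_phylotypes)]
    if config.regime == "turnover":
        upper = limits + config.niche_width
    elif config.regime == "nested":
        upper = np.full_like(limits, max_ph)
    else:
        upper = np.full_like(limits, 14.0)
    optima = limits + config.dominance_offset

    # site-level propagule availability: independent of pH, it punches the
    # dispersal/soil-type holes real surveys show on top of the pH filter
    available = rng.random((config.n_sites, config.n_phylotypes)) < config.site_availability_prob
    site_index = {sid: k for k, sid in enumerate(site_ids)}

    records: list[SampleRecord] = []
    for row in samples.itertuples(index=False):
        ph = row.ph
        p_eff = np.full(config.n_phylotypes, config.occupancy_prob)
        if config.regime == "nested":
            eligible = limits <= ph
            if config.occupancy_ramp > 0:
                # propagule density thins toward the niche edge, so holes
                # concentrate near each phylotype's tolerance boundary
                p_eff = p_eff * (1.0 - np.exp(-(ph - limits) / config.occupancy_ramp))
        elif config.regime == "turnover":
            eligible = (limits <= ph) & (ph <= limits + config.niche_width)
        else:
            eligible = np.ones(config.n_phylotypes, dtype=bool)
        eligible = eligible & available[site_index[row.site]]
        occupied = eligible & (rng.random(config.n_phylotypes) < p_eff)
        idx = np.flatnonzero(occupied)
        if len(idx) == 0:
            continue
        if config.dominance_shift:
            # floor keeps off-optimum colonists detectable (incidence stays
            # nested) while the Gaussian part shifts who dominates
            w = config.dominance_floor + np.exp(
                -((ph - optima[idx]) ** 2) / (2.0 * config.dominance_width**2)
            )
            w = w / w.sum()
        else:
            w = np.full(len(idx), 1.0 / len(idx))
        clones = rng.multinomial(config.clones_per_sample, w)
        if config.detection == "complete":
            clones = np.maximum(clones, 1)
        for j, c in zip(idx, clones):
            if c == 0:  # colonist missed by the clone library
                continue
            records.append(
                SampleRecord(
                    sample_id=row.sample_id,
                    group_id=row.site,
                    ph=ph,
                    phylotype_id=phylo_ids[j],
                    clone_count=int(c),
                )
            )

    truth = SimulationTruth(
        phylotypes=pd.DataFrame(
            {
                "phylotype": phylo_ids,
                "lower_limit": limits,
                "upper_limit": upper,
                "abundance_optimum": optima,
            }
        ),
        samples=samples,
    )
    return SampleTable(records=records), truth


def recovery_suite(
    config: SimulationConfig,
    n_replicates: int = 20,
    seed: int | None = None,
    n_null: int = 1000,
) -> pd.DataFrame:
    """Run the full pipeline on replicate simulations and summarize what it
    recovers: incidence-nestedness Z (columns), abundance-nestedness Z (rows),
    SDR percentage contributions, generality correlation, and the agreement
    between estimated and true tolerance limits.
    """
    from nestgrad.pipeline import analyze_table  # local import: avoid cycle

    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(n_replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = SimulationConfig(**{**config.__dict__, "seed": rep_seed})
        table, truth = simulate(cfg)
        rpt = analyze_table(table, n_null=n_null, n_perm=0, seed=rep_seed)
        prof = {p.phylotype_id: p for p in generality_profiles(table)}
        truth_df = truth.phylotypes
        est_min = np.array(
            [prof[p].min_ph if p in prof else np.nan for p in truth_df["phylotype"]]
        )
        ok = ~np.isnan(est_min)
        limit_r = (
            float(np.corrcoef(est_min[ok], truth_df["lower_limit"][ok])[0, 1])
            if ok.sum() >= 3
            else np.nan
        )
        rows.append(
            {
                "replicate": rep,
                "seed": rep_seed,
                "nodf_columns": rpt["nodf_columns"].observed,
                "nodf_z": rpt["nodf_columns"].z,
                "nodf_p_upper": rpt["nodf_columns"].p_upper,
                "wnodf_rows": rpt["wnodf_rows"].observed,
                "wnodf_z": rpt["wnodf_rows"].z,
                "wnodf_p_lower": rpt["wnodf_rows"].p_lower,
                "sdr_binary_turnover": rpt["sdr_binary"].pct_turnover,
                "sdr_binary_nestedness": rpt["sdr_binary"].pct_nestedness,
                "sdr_abundance_turnover": rpt["sdr_abundance"].pct_turnover,
                "sdr_abundance_nestedness": rpt["sdr_abundance"].pct_nestedness,
                "generality_r": rpt["generality"][0],
                "generality_p": rpt["generality"][1],
                "tolerance_limit_recovery_r": limit_r,
            }
        )
    return pd.DataFrame(rows)
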