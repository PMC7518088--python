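"""Synthetic produced-water amplicon datasets with ground truth.

The generator emulates the statistical structure of a repetitive-volume
filtration study of a single formation-water source: a shared "true"
community, a kit/lab contaminant pool that is all a blank ever sees,
per-sample biomass decoupled from (or optionally coupled to) filtered
volume, contaminant read fractions that grow as biomass shrinks, and
triplicate qPCR crossing points generated from total template through a
log-linear standard curve.

Generative model, per sample i with filtered volume v_i:

* community compositions pi_true ~ Dirichlet(alpha_true), pi_cont ~
  Dirichlet(alpha_cont); an optional set of shared OTUs receives a fixed
  slice of both compositions (modelling the ubiquitous contaminant that
  shows up in every sample);
* formation biomass B_i = Z_i * exp(N(mu_B, sigma_B)) * (v_i/500)^gamma
  copies/uL, where Z_i ~ Bernoulli(1 - capture_failure_rate) models
  filters that capture essentially no formation biomass (gamma = 0
  decouples biomass from volume); blanks have B = 0;
* contaminant load C ~ exp(N(mu_C, sigma_C)) drawn once per extraction
  batch (default: a single batch, i.e. one kit lot for the whole run);
* contaminant read fraction f_i = C_i / (B_i + C_i), so f rises as
  biomass falls and f = 1 for blanks;
* read counts ~ Multinomial(N_i, (1-f_i) pi_true + f_i pi_cont) with
  depth N_i lognormal; a Dirichlet-multinomial overdispersion knob adds
  extra-multinomial noise;
* Cp replicates = b + m log10(B_i + C_i) + N(0, sigma_cp).

Ground truth (true biomass, contaminant fraction, per-OTU origin) is
returned alongside the tables for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Optional

import numpy as np
import pandas as pd

from .io import (CpTable, Metadata, OtuTable, write_cp_table, write_metadata,
                 write_otu_table)

__all__ = [
    "SyntheticConfig", "SyntheticTruth", "GeneratedDataset",
    "generate_dataset", "expected_contaminant_fraction",
    "study_like_config", "write_dataset",
]

#: Filtered volumes (mL) and replicate filters per volume: ten bins from
#: 100 to 1000 mL with 4-5 filters each (49 samples), plus 8 blanks.
DEFAULT_VOLUMES: dict = {1000: 5, 900: 5, 800: 5, 700: 5, 600: 5,
                         500: 5, 400: 5, 300: 5, 200: 4, 100: 5}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study generator.

    Defaults are calibrated to the produced-water conditions the
    pipeline targets: ~96% amplification efficiency (slope -3.42),
    captured-biomass crossing points in the mid-20s, blank-level
    crossing points in the low-to-mid 30s, and roughly half of the
    equal-volume filters capturing essentially no formation biomass
    regardless of volume.
    """

    volumes: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_VOLUMES))
    n_blanks: int = 8

    # community sizes and concentrations
    n_true_otus: int = 719
    n_contaminant_otus: int = 156
    n_shared_otus: int = 1           # OTUs present in both pools (the
                                     # every-sample contaminant)
    shared_otu_weight: float = 0.05  # composition mass given to shared OTUs
    dirichlet_alpha_true: float = 0.15
    dirichlet_alpha_cont: float = 0.3

    # biomass model (copies/uL, natural-log scale)
    biomass_log_mean: float = 9.1    # exp -> ~9000 copies/uL, Cp ~ 26.5
    biomass_log_sd: float = 1.4
    capture_failure_rate: float = 0.45
    volume_coupling: float = 0.0     # gamma: 0 = biomass independent of volume
    carboy_multipliers: Optional[Mapping[str, float]] = None  # short-timescale
                                     # source variability, e.g. {"C3": 0.01}

    # contaminant load (copies/uL, natural-log scale)
    contaminant_log_mean: float = 4.7  # exp -> ~110 copies/uL, Cp ~ 33
    contaminant_log_sd: float = 1.0
    contaminant_batches: Optional[Mapping[str, str]] = None  # sample -> batch
                                     # label; None = every extraction its own
                                     # draw (blanks in the study span several
                                     # Cp cycles, i.e. loads vary per filter)
    blank_contaminant_scale: float = 2.0  # blanks process 2 L of lab water /
                                     # bare filters and accumulate more
                                     # contaminant than a sample extraction

    # sequencing depth (reads/sample, natural-log scale)
    depth_log_mean: float = 9.0      # exp -> ~8100 reads
    depth_log_sd: float = 0.8
    overdispersion: float = 0.0      # Dirichlet-multinomial scale; 0 = plain
                                     # multinomial

    # qPCR generation
    curve_slope: float = -3.42       # efficiency ~96%
    curve_intercept: float = 40.0
    cp_noise_sd: float = 0.3
    n_replicates: int = 3
    lab_threshold_cp: float = 31.0   # simulated laboratory amplification flag
    lab_flag_noise_sd: float = 1.5   # library amplification success tracks Cp
                                     # only loosely; jitter on the lab cut

    # fixture control
    ensure_coverage: bool = False    # force every configured OTU to be
                                     # observed (adds single top-up reads)
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("need at least one Cp replicate per sample")
        if self.dirichlet_alpha_true <= 0 or self.dirichlet_alpha_cont <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        if self.volume_coupling < 0:
            raise ValueError("volume-coupling exponent must be >= 0")
        if not (0 <= self.capture_failure_rate <= 1):
            raise ValueError("capture_failure_rate must lie in [0, 1]")
        if self.n_shared_otus > self.n_contaminant_otus:
            raise ValueError("shared OTUs are drawn from the contaminant pool")
        if any(n < 1 for n in self.volumes.values()) or self.n_blanks < 1:
            raise ValueError("every volume bin and the blank set need >= 1 sample")


@dataclass
class SyntheticTruth:
    """Ground truth emitted with every generated dataset.

    ``per_sample`` columns: true_biomass (copies/uL; 0 for blanks),
    contaminant_load, contaminant_fraction f = C/(B+C) (1 for blanks),
    is_contaminant_dominated (f > 0.5), depth, is_blank.
    ``otu_origin``: OTU id -> "true-community" | "contaminant-pool" |
    "shared".
    """

    per_sample: pd.DataFrame
    otu_origin: pd.Series


class GeneratedDataset(NamedTuple):
    otu: OtuTable
    cp: CpTable
    metadata: Metadata
    truth: SyntheticTruth


def expected_contaminant_fraction(B: float, C: float) -> float:
    """f = C / (B + C): the expected share of reads that are contaminant,
    monotone decreasing in true biomass B (1.0 for a blank)."""
    if B < 0 or C < 0:
        raise ValueError("biomass and contaminant load must be non-negative")
    if B + C == 0:
        raise ValueError("B + C must be positive")
    return C / (B + C)


def _compositions(cfg: SyntheticConfig, rng) -> tuple:
    """Build pi_true and pi_cont over the global OTU id list."""
    true_ids = [f"OTU_T{i + 1:04d}" for i in range(cfg.n_true_otus)]
    shared_ids = [f"OTU_S{i + 1:02d}" for i in range(cfg.n_shared_otus)]
    cont_only = [f"OTU_C{i + 1:04d}"
                 for i in range(cfg.n_contaminant_otus - cfg.n_shared_otus)]
    otu_ids = true_ids + shared_ids + cont_only
    n = len(otu_ids)
    w = cfg.shared_otu_weight if cfg.n_shared_otus else 0.0

    pi_true = np.zeros(n)
    pi_true[:cfg.n_true_otus] = (1 - w) * rng.dirichlet(
        np.full(cfg.n_true_otus, cfg.dirichlet_alpha_true))
    pi_cont = np.zeros(n)
    n_co = len(cont_only)
    if n_co:
        pi_cont[cfg.n_true_otus + cfg.n_shared_otus:] = (1 - w) * rng.dirichlet(
            np.full(n_co, cfg.dirichlet_alpha_cont))
    for j in range(cfg.n_shared_otus):
        pi_true[cfg.n_true_otus + j] = w / cfg.n_shared_otus
        pi_cont[cfg.n_true_otus + j] = w / cfg.n_shared_otus
    origin = pd.Series(
        ["true-community"] * cfg.n_true_otus + ["shared"] * cfg.n_shared_otus
        + ["contaminant-pool"] * n_co, index=otu_ids)
    return otu_ids, pi_true / pi_true.sum(), pi_cont / pi_cont.sum(), origin


def _draw_counts(rng, depth: int, p: np.ndarray, overdispersion: float) -> np.ndarray:
    if overdispersion > 0:
        q = np.zeros_like(p)
        nz = p > 0
        q[nz] = rng.dirichlet(p[nz] / overdispersion)
        p = q
    return rng.multinomial(depth, p)


def generate_dataset(config: SyntheticConfig | None = None,
                     seed: Optional[int] = None) -> GeneratedDataset:
    """Generate one complete synthetic study: OTU counts, Cp triplicates,
    metadata and ground truth.  The same seed gives bit-identical output;
    ``seed`` overrides ``config.seed`` when given."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    otu_ids, pi_true, pi_cont, origin = _compositions(cfg, rng)

    sample_ids, volumes = [], []
    i = 0
    for vol in sorted(cfg.volumes, reverse=True):
        for _ in range(cfg.volumes[vol]):
            i += 1
            sample_ids.append(f"S{i:03d}")
            volumes.append(int(vol))
    blank_ids = [f"BLK{j + 1}" for j in range(cfg.n_blanks)]
    all_ids = sample_ids + blank_ids
    carboys = [f"C{1 + (j % 6)}" for j in range(len(sample_ids))]
    rng.shuffle(carboys)

    # contaminant load per extraction batch (default: one draw per filter)
    if cfg.contaminant_batches is None:
        batch_of = {sid: sid for sid in all_ids}
    else:
        batch_of = {sid: cfg.contaminant_batches.get(sid, "batch1") for sid in all_ids}
    load_of_batch = {
        b: float(np.exp(rng.normal(cfg.contaminant_log_mean, cfg.contaminant_log_sd)))
        for b in sorted(set(batch_of.values()))}

    n_samples = len(all_ids)
    captured = rng.random(len(sample_ids)) >= cfg.capture_failure_rate
    b_draw = np.exp(rng.normal(cfg.biomass_log_mean, cfg.biomass_log_sd,
                               size=len(sample_ids)))
    biomass = np.zeros(n_samples)
    mult = cfg.carboy_multipliers or {}
    for j, (sid, vol) in enumerate(zip(sample_ids, volumes)):
        scale = (vol / 500.0) ** cfg.volume_coupling if vol > 0 else 0.0
        biomass[j] = captured[j] * b_draw[j] * scale * mult.get(carboys[j], 1.0)
    cont = np.array([load_of_batch[batch_of[sid]] for sid in all_ids])
    cont[len(sample_ids):] *= cfg.blank_contaminant_scale
    frac = cont / (biomass + cont)

    depth = np.maximum(
        1, np.round(np.exp(rng.normal(cfg.depth_log_mean, cfg.depth_log_sd,
                                      size=n_samples)))).astype(int)
    counts = np.zeros((n_samples, len(otu_ids)), dtype=np.int64)
    for j in range(n_samples):
        p = (1.0 - frac[j]) * pi_true + frac[j] * pi_cont
        counts[j] = _draw_counts(rng, depth[j], p, cfg.overdispersion)

    if cfg.ensure_coverage:
        n_blank_rows = len(blank_ids)
        cont_cols = np.flatnonzero((origin != "true-community").to_numpy())
        true_cols = np.flatnonzero((origin == "true-community").to_numpy())
        blank_rows = np.arange(len(sample_ids), n_samples)
        sample_rows = np.arange(len(sample_ids))
        for c in cont_cols:
            if counts[blank_rows, c].sum() == 0:
                counts[rng.choice(blank_rows), c] += 1
        for c in true_cols:
            if counts[sample_rows, c].sum() == 0:
                counts[rng.choice(sample_rows), c] += 1

    # qPCR: Cp from total template through the log-linear curve
    total = biomass + cont
    cp_base = cfg.curve_intercept + cfg.curve_slope * np.log10(total)
    replicates = {}
    for j, sid in enumerate(all_ids):
        reps = cp_base[j] + rng.normal(0.0, cfg.cp_noise_sd, size=cfg.n_replicates) \
            if cfg.cp_noise_sd > 0 else np.full(cfg.n_replicates, cp_base[j])
        replicates[sid] = list(np.clip(reps, 0.01, 59.99))

    avg_cp = np.array([float(np.mean(replicates[sid])) for sid in all_ids])
    lab_flag = avg_cp < cfg.lab_threshold_cp + rng.normal(
        0.0, cfg.lab_flag_noise_sd, size=n_samples)

    records = []
    for j, sid in enumerate(all_ids):
        is_blank = j >= len(sample_ids)
        records.append({
            "sample_id": sid,
            "volume_ml": 0 if is_blank else volumes[j],
            "is_blank": is_blank,
            "blank_type": (("filtered-water", "unused-filter")[
                (j - len(sample_ids)) % 2] if is_blank else None),
            "carboy_id": None if is_blank else carboys[j],
            "lab_amplified": bool(lab_flag[j]),
        })
    metadata = Metadata.from_records(records)

    otu = OtuTable(pd.DataFrame(counts, index=all_ids, columns=otu_ids),
                   unit="counts")
    cp = CpTable(replicates)
    truth = SyntheticTruth(
        per_sample=pd.DataFrame({
            "true_biomass": biomass,
            "contaminant_load": cont,
            "contaminant_fraction": frac,
            "is_contaminant_dominated": frac > 0.5,
            "depth": depth,
            "is_blank": [sid in blank_ids for sid in all_ids],
        }, index=all_ids),
        otu_origin=origin)
    return GeneratedDataset(otu=otu, cp=cp, metadata=metadata, truth=truth)


def study_like_config(**overrides) -> SyntheticConfig:
    """The default configuration with coverage enforcement switched on,
    so the generated dataset's distinct-OTU totals equal the configured
    pool sizes exactly (875 OTUs overall, 156 observed in blanks, 719
    never seen in a blank)."""
    params = dict(ensure_coverage=True)
    params.update(overrides)
    return SyntheticConfig(**params)


def write_dataset(dataset: GeneratedDataset, out_dir) -> dict:
    """Write the four TSVs plus ground truth to a directory; returns the
    path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu": out / "otu.tsv",
        "cp": out / "cp.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.tsv",
    }
    write_otu_table(dataset.otu, paths["otu"])
    write_cp_table(dataset.cp, paths["cp"])
    write_metadata(dataset.metadata, paths["metadata"])
    truth = dataset.truth.per_sample.copy()
    truth.insert(0, "sample_id", truth.index)
    truth.to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
    return paths
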