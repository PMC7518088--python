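"""End-to-end QC model for low-biomass amplicon studies.

:class:`LowBiomassQC` bundles the four input tables and runs the whole
chain — replicate averaging, blank-derived thresholding, detection
classification, blank-OTU decontamination, alpha diversity, Bray-Curtis
/ NMDS ordination and the volume statistics — in one :meth:`~LowBiomassQC.fit`
call.  The returned :class:`LowBiomassQCResults` carries every
intermediate product, a text :meth:`~LowBiomassQCResults.summary`, plot
helpers, and :meth:`~LowBiomassQCResults.save_report` for the on-disk
report bundle.

Both competing detection-limit definitions — the laboratory's own
amplification flag (when supplied) and the blank-derived minimum-Cp rule
— are always evaluated side by side, before and after decontamination;
the blank-derived rule is the one this package recommends.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__ as _version
from . import decontam as _decontam
from . import diversity as _diversity
from . import qpcr as _qpcr
from . import stats as _stats
from .io import (CpTable, Metadata, OtuTable, TaxonomyTable, read_cp_table,
                 read_metadata, read_otu_table, read_standard_curve_points,
                 read_taxonomy, write_otu_table)

__all__ = ["LowBiomassQC", "LowBiomassQCResults"]


class LowBiomassQC:
    """Quality-control model for a blank-anchored low-biomass study.

    Parameters
    ----------
    otu : OtuTable
        Raw read counts, samples x OTUs.
    cp : CpTable
        Triplicate qPCR crossing points per sample.
    metadata : Metadata
        Volumes, blank flags and (optionally) the laboratory's own
        amplification verdicts.
    taxonomy : TaxonomyTable, optional
        Used only to name the top taxa in the report.
    curve : qpcr.StandardCurve, optional
        When given, verdicts also carry absolute 16S copies/uL; the
        thresholding itself runs entirely on Cp values.
    """

    def __init__(self, otu: OtuTable, cp: CpTable, metadata: Metadata,
                 taxonomy: Optional[TaxonomyTable] = None, curve=None):
        if otu.unit != "counts":
            raise ValueError("the QC model requires a counts-unit OTU table "
                             "(decontamination operates on raw reads)")
        common = [s for s in otu.sample_ids if s in cp and s in metadata]
        self.skipped = sorted(set(otu.sample_ids) | set(cp.sample_ids)
                              | set(metadata.sample_ids))
        self.skipped = [s for s in self.skipped if s not in common]
        blanks = [s for s in common if metadata.is_blank(s)]
        nonblanks = [s for s in common if not metadata.is_blank(s)]
        if not blanks:
            raise ValueError(
                "no blank samples shared by the OTU, Cp and metadata tables: "
                "the blank-anchored QC procedure requires submitted blanks")
        if len(nonblanks) < 3:
            raise ValueError(f"need at least 3 non-blank samples shared by all "
                             f"tables, got {len(nonblanks)}")
        self.otu = otu.select_samples(common)
        self.cp = cp
        self.metadata = metadata
        self.taxonomy = taxonomy
        self.curve = curve
        self._common = common
        self._blanks = blanks
        self._nonblanks = nonblanks

    # ------------------------------------------------------------------
    @classmethod
    def from_paths(cls, otu_path, cp_path, metadata_path, taxonomy_path=None,
                   curve_path=None, orientation: str = "samples") -> "LowBiomassQC":
        """Build the model straight from the four TSV files."""
        curve = None
        if curve_path is not None:
            curve = _qpcr.fit_standard_curve(read_standard_curve_points(curve_path))
        taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path else None
        return cls(read_otu_table(otu_path, orientation=orientation),
                   read_cp_table(cp_path), read_metadata(metadata_path),
                   taxonomy=taxonomy, curve=curve)

    @classmethod
    def from_synthetic(cls, dataset, curve=None) -> "LowBiomassQC":
        """Build the model from a :func:`blankgate.simulate.generate_dataset`
        output."""
        return cls(dataset.otu, dataset.cp, dataset.metadata, curve=curve)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0, n_permutations: int = 999,
            nmds_starts: int = 20, nmds_k: int = 2,
            decontam_min_count: int = 1) -> "LowBiomassQCResults":
        """Run the full QC chain and return the results object.

        ``seed`` drives every stochastic step (permutation tests, NMDS
        starts) so a fit is reproducible bit for bit.
        """
        rng = np.random.default_rng(seed)
        log = [f"blankgate {_version}", f"seed={seed}",
               f"samples={len(self._common)} ({len(self._nonblanks)} samples "
               f"+ {len(self._blanks)} blanks)"]
        if self.skipped:
            log.append(f"skipped (not in all tables): {', '.join(self.skipped)}")

        # --- qPCR stage -------------------------------------------------
        threshold = _qpcr.blank_threshold(self.cp, self.metadata)
        log.append(f"blank-derived Cp threshold = {threshold:.4g} "
                   f"(minimum average Cp over {len(self._blanks)} blanks)")
        blank_cls = _qpcr.classify_samples(self.cp, self.metadata, threshold,
                                           curve=self.curve)
        verdicts = _qpcr.verdicts_to_frame(blank_cls.verdicts).loc[self._common]
        lab_cls = _qpcr.lab_flag_verdicts(self.cp, self.metadata, curve=self.curve)
        lab_frame = (_qpcr.verdicts_to_frame(lab_cls.verdicts)
                     if lab_cls.verdicts else None)

        volume_regression = _qpcr.volume_cp_regression(self.metadata, self.cp)
        vols = pd.Series({s: self.metadata.volume(s) for s in self._nonblanks})
        cps = verdicts.loc[self._nonblanks, "avg_cp"]
        volume_kruskal = _stats.kruskal_wallis(cps.to_numpy(), vols.to_numpy())
        log.append(f"volume vs Cp: OLS R2={volume_regression.r2:.4g}, "
                   f"KW H={volume_kruskal.H_statistic:.4g} "
                   f"p={volume_kruskal.p_value:.4g}")

        # --- community stage (pre-decontamination, blanks included) ----
        percent_pre = _decontam.to_percent_abundance(self.otu)
        alpha = _diversity.alpha_diversity(percent_pre)
        dist_pre = _diversity.distance_matrix(percent_pre)

        groupings = {"blank-derived": verdicts["above_detection"].map(
            {True: "above", False: "below"})}
        if lab_frame is not None:
            groupings["lab-flag"] = lab_frame["above_detection"].map(
                {True: "above", False: "below"})

        permanova: dict = {}
        for name, labels in groupings.items():
            permanova[(name, "pre")] = self._permanova_or_none(
                dist_pre, labels, n_permutations, rng, log, f"{name}/pre")

        nmds_results = {"pre": _stats.nmds(
            dist_pre, k=nmds_k, n_starts=nmds_starts,
            seed=int(rng.integers(2 ** 31)))}
        log.append(f"NMDS (pre-decontam) stress={nmds_results['pre'].stress:.4g}")

        # --- decontamination stage --------------------------------------
        blank_otus = _decontam.blank_otu_set(self.otu, self.metadata,
                                             min_count=decontam_min_count)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-read samples handled below
            clean = _decontam.remove_contaminants(self.otu, self.metadata,
                                                  min_count=decontam_min_count)
        report = _decontam.decontam_report(self.otu, clean)
        log.append(f"decontamination: {report.totals['distinct_otus_before']} "
                   f"distinct OTUs -> {report.totals['distinct_otus_after']} "
                   f"({len(blank_otus)} blank OTUs removed)")

        empty_after = [s for s in clean.sample_ids
                       if clean.data.loc[s].sum() == 0]
        post_ids = [s for s in clean.sample_ids if s not in empty_after]
        if empty_after:
            log.append("samples with zero reads after removal (excluded from "
                       "post-decontam ordination): " + ", ".join(empty_after))
        dist_post = nmds_post = None
        if len(post_ids) >= 3:
            percent_post = _decontam.to_percent_abundance(
                clean.select_samples(post_ids))
            dist_post = _diversity.distance_matrix(percent_post)
            for name, labels in groupings.items():
                permanova[(name, "post")] = self._permanova_or_none(
                    dist_post, labels.loc[post_ids], n_permutations, rng, log,
                    f"{name}/post")
            nmds_post = _stats.nmds(dist_post, k=nmds_k, n_starts=nmds_starts,
                                    seed=int(rng.integers(2 ** 31)))
            log.append(f"NMDS (post-decontam) stress={nmds_post.stress:.4g}")
        nmds_results["post"] = nmds_post

        return LowBiomassQCResults(
            model=self, threshold=threshold, verdicts=verdicts,
            lab_verdicts=lab_frame, skipped=list(self.skipped) + blank_cls.skipped,
            volume_regression=volume_regression, volume_kruskal=volume_kruskal,
            alpha=alpha, blank_otus=blank_otus, clean_otu=clean,
            decontam=report, distances={"pre": dist_pre, "post": dist_post},
            permanova=permanova, nmds=nmds_results, groupings=groupings,
            seed=seed, n_permutations=n_permutations, log=log,
            zero_read_samples=empty_after)

    @staticmethod
    def _permanova_or_none(dist, labels, n_permutations, rng, log, tag):
        labels = labels.loc[list(dist.ids)]
        if labels.nunique() < 2:
            log.append(f"PERMANOVA {tag}: single group, not testable")
            return None
        res = _stats.permanova(dist, labels, n_permutations=n_permutations,
                               seed=int(rng.integers(2 ** 31)))
        log.append(f"PERMANOVA {tag}: F={res.pseudo_F:.4g} R2={res.r2:.4g} "
                   f"p={res.p_value:.4g}")
        return res


@dataclass
class LowBiomassQCResults:
    """Everything the QC chain produced; see :meth:`summary` for the
    human-readable digest."""

    model: LowBiomassQC
    threshold: float
    verdicts: pd.DataFrame
    lab_verdicts: Optional[pd.DataFrame]
    skipped: list
    volume_regression: object
    volume_kruskal: object
    alpha: pd.DataFrame
    blank_otus: frozenset
    clean_otu: OtuTable
    decontam: object
    distances: dict
    permanova: dict
    nmds: dict
    groupings: dict
    seed: int
    n_permutations: int
    log: list = field(default_factory=list)
    zero_read_samples: list = field(default_factory=list)

    # ------------------------------------------------------------------
    def alpha_by_volume(self, statistic: str = "shannon") -> pd.DataFrame:
        """Boxplot-style per-volume summary of an alpha-diversity column."""
        return _diversity.volume_group_summary(self.alpha[statistic],
                                               self.model.metadata)

    @property
    def n_above(self) -> int:
        return int(self.verdicts["above_detection"].sum())

    @property
    def n_below(self) -> int:
        return int((~self.verdicts["above_detection"]).sum())

    # ------------------------------------------------------------------
    def summary(self) -> str:
        t = self.decontam.totals
        lines = []
        w = 78
        lines.append("Low-biomass amplicon QC (blank-anchored)".center(w))
        lines.append("=" * w)
        lines.append(f"{'No. samples:':<34}{len(self.verdicts)} "
                     f"({len(self.model._nonblanks)} samples + "
                     f"{len(self.model._blanks)} blanks)")
        lines.append(f"{'Blank-derived Cp threshold:':<34}{self.threshold:.4g}"
                     f"  [recommended]")
        lines.append(f"{'Above / below detection:':<34}{self.n_above} / "
                     f"{self.n_below}")
        avg = self.verdicts["avg_cp"]
        lines.append(f"{'Average-Cp range:':<34}{avg.min():.4g} - {avg.max():.4g}")
        lines.append("-" * w)
        lines.append(f"{'Volume vs Cp (OLS):':<34}R2 = "
                     f"{self.volume_regression.r2:.4g}, slope = "
                     f"{self.volume_regression.slope:.3g} cycles/mL")
        lines.append(f"{'Volume vs Cp (Kruskal-Wallis):':<34}H = "
                     f"{self.volume_kruskal.H_statistic:.4g}, df = "
                     f"{self.volume_kruskal.df}, p = "
                     f"{self.volume_kruskal.p_value:.4g}")
        lines.append("-" * w)
        lines.append(f"{'Blank-observed (removed) OTUs:':<34}{len(self.blank_otus)}")
        lines.append(f"{'Distinct OTUs before / after:':<34}"
                     f"{t['distinct_otus_before']} / {t['distinct_otus_after']}")
        lines.append(f"{'Sequences per sample (before):':<34}"
                     f"{t['min_sequences_before']:.0f} - "
                     f"{t['max_sequences_before']:.0f}")
        lines.append(f"{'Sequences per sample (after):':<34}"
                     f"{t['min_sequences_after']:.0f} - "
                     f"{t['max_sequences_after']:.0f}")
        lines.append("-" * w)
        lines.append("PERMANOVA (Bray-Curtis, above vs below detection)")
        lines.append(f"  {'grouping':<16}{'stage':<8}{'pseudo-F':>10}{'R2':>8}"
                     f"{'p':>9}{'perms':>7}")
        for (name, stage), res in sorted(self.permanova.items()):
            if res is None:
                lines.append(f"  {name:<16}{stage:<8}{'-- single group --':>27}")
            else:
                lines.append(f"  {name:<16}{stage:<8}{res.pseudo_F:>10.3f}"
                             f"{res.r2:>8.3f}{res.p_value:>9.4f}"
                             f"{res.n_permutations:>7d}")
        lines.append("-" * w)
        for stage in ("pre", "post"):
            r = self.nmds.get(stage)
            if r is not None:
                lines.append(f"{f'NMDS stress ({stage}-decontam):':<34}"
                             f"{r.stress:.4g}  (k={r.coordinates.shape[1]}, "
                             f"{r.n_starts} starts)")
        if self.skipped:
            lines.append(f"{'Skipped samples:':<34}{', '.join(map(str, self.skipped))}")
        lines.append("=" * w)
        return "\n".join(lines)

    def __str__(self):
        return self.summary()

    # ------------------------------------------------------------------
    def to_report_dict(self) -> dict:
        """JSON-serialisable digest of the full results."""
        def _permanova_dict(res):
            if res is None:
                return None
            return {"pseudo_F": res.pseudo_F, "r2": res.r2,
                    "p_value": res.p_value,
                    "n_permutations": res.n_permutations}

        return {
            "version": _version,
            "seed": self.seed,
            "threshold": {"value": self.threshold, "source": "blank-derived",
                          "recommended": True},
            "n_samples": len(self.verdicts),
            "n_above": self.n_above, "n_below": self.n_below,
            "avg_cp_range": [float(self.verdicts["avg_cp"].min()),
                             float(self.verdicts["avg_cp"].max())],
            "volume_regression": {"r2": self.volume_regression.r2,
                                  "slope": self.volume_regression.slope,
                                  "intercept": self.volume_regression.intercept},
            "volume_kruskal": {"H": self.volume_kruskal.H_statistic,
                               "df": self.volume_kruskal.df,
                               "p_value": self.volume_kruskal.p_value},
            "decontam_totals": self.decontam.totals,
            "n_blank_otus": len(self.blank_otus),
            "permanova": {f"{name}/{stage}": _permanova_dict(res)
                          for (name, stage), res in sorted(self.permanova.items())},
            "nmds_stress": {stage: (None if r is None else r.stress)
                            for stage, r in self.nmds.items()},
            "skipped": list(map(str, self.skipped)),
            "zero_read_samples": list(map(str, self.zero_read_samples)),
            "verdicts": {
                sid: {"avg_cp": float(row["avg_cp"]),
                      "above_detection": bool(row["above_detection"])}
                for sid, row in self.verdicts.iterrows()},
        }

    def save_report(self, out_dir) -> dict:
        """Write the report bundle (TSVs, report.json, run.log); returns
        the path map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        paths["verdicts"] = out / "verdicts.tsv"
        self.verdicts.to_csv(paths["verdicts"], sep="\t", lineterminator="\n",
                             index_label="sample_id")
        paths["clean_otu"] = out / "clean_otu.tsv"
        write_otu_table(self.clean_otu, paths["clean_otu"])
        paths["table1"] = out / "table1.tsv"
        self.decontam.per_sample.to_csv(paths["table1"], sep="\t",
                                        lineterminator="\n",
                                        index_label="sample_id")
        paths["alpha"] = out / "alpha.tsv"
        self.alpha.to_csv(paths["alpha"], sep="\t", lineterminator="\n",
                          index_label="sample_id")
        dm = self.distances["pre"]
        paths["bray"] = out / "bray.tsv"
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            paths["bray"], sep="\t", lineterminator="\n", index_label="sample_id")
        nm = self.nmds["post"] or self.nmds["pre"]
        paths["nmds"] = out / "nmds.tsv"
        nm.coordinates.to_csv(paths["nmds"], sep="\t", lineterminator="\n",
                              index_label="sample_id")

        rows = [{"test": "ols_volume_cp", "statistic": self.volume_regression.slope,
                 "r2": self.volume_regression.r2, "p_value": float("nan")},
                {"test": "kruskal_volume_cp",
                 "statistic": self.volume_kruskal.H_statistic,
                 "r2": float("nan"), "p_value": self.volume_kruskal.p_value}]
        for (name, stage), res in sorted(self.permanova.items()):
            if res is not None:
                rows.append({"test": f"permanova_{name}_{stage}",
                             "statistic": res.pseudo_F, "r2": res.r2,
                             "p_value": res.p_value})
        paths["stats"] = out / "stats.tsv"
        pd.DataFrame(rows).to_csv(paths["stats"], sep="\t", index=False,
                                  lineterminator="\n", float_format="%.10g")

        paths["report"] = out / "report.json"
        paths["report"].write_text(
            json.dumps(self.to_report_dict(), indent=2, sort_keys=True) + "\n")
        paths["log"] = out / "run.log"
        paths["log"].write_text("\n".join(self.log) + "\n")
        return paths

    # ------------------------------------------------------------------
    def plot_nmds(self, stage: str = "post", grouping: str = "blank-derived",
                  ax=None):
        from .plotting import plot_nmds
        result = self.nmds[stage] if self.nmds.get(stage) else self.nmds["pre"]
        labels = self.groupings[grouping].loc[result.coordinates.index]
        res = self.permanova.get((grouping, stage))
        return plot_nmds(result, labels, permanova=res, ax=ax)

    def plot_alpha_by_volume(self, statistic: str = "shannon", ax=None):
        from .plotting import plot_by_volume
        return plot_by_volume(self.alpha[statistic], self.model.metadata,
                              ylabel=statistic, ax=ax)

    def plot_cp_by_volume(self, ax=None):
        from .plotting import plot_by_volume
        return plot_by_volume(self.verdicts["avg_cp"], self.model.metadata,
                              ylabel="average Cp (cycles)", ax=ax,
                              hline=self.threshold)
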