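"""The dimer-enrichment model and its fitted results.

:class:`DimerEnrichmentModel` is built from data (genome, motif library,
target/control region sets) plus a :class:`~dimerscan.config.RunConfig`;
``fit()`` executes the pipeline --- threshold calibration, scanning, complex
enumeration, instance counting, Bernoulli testing, Bonferroni correction,
clustering --- and returns a :class:`DimerResults` carrying the predictions
table, the clusters, diagnostics (Q-Q table, spacing profiles) and output
writers.
"""

from __future__ import annotations

import logging
import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import DimerCluster, cluster_all
from .complexes import default_min_spacing, enumerate_complexes, pair_instances
from .config import RunConfig
from .enrichment import EnrichmentResult, bonferroni, possible_placements, test_complex
from .flexibility import (FlexibilityStats, SpacingGroup, flexibility_stats,
                          group_predictions, iqr_outlier_filter, trims_for)
from .motifs import Motif, calibrate_threshold, parse_motifs, write_transfac
from .regions import DatasetBundle, build_targets, merge_replicates, read_bed
from .scan import Genome, background_frequencies, scan

logger = logging.getLogger(__name__)


class DimerEnrichmentModel:
    """Enrichment model for rigidly spaced motif complexes.

    Parameters
    ----------
    genome : Genome or str
        Indexed FASTA (or its path).
    motifs : list of Motif
        The motif library.
    bundle : DatasetBundle
        Target region sets plus the control universe (union of all inputs).
    config : RunConfig, optional
        Screening scope and parameters; defaults are used when omitted.
    """

    def __init__(self, genome, motifs: list[Motif], bundle: DatasetBundle,
                 config: RunConfig | None = None):
        self.genome = genome if isinstance(genome, Genome) else Genome(genome)
        self.motifs = list(motifs)
        self.motif_by_id = {m.id: m for m in self.motifs}
        if len(self.motif_by_id) != len(self.motifs):
            raise ValueError("duplicate motif ids in the library")
        self.bundle = bundle
        self.config = config or RunConfig()
        sizes = self.genome.chrom_sizes
        self.bundle = DatasetBundle(
            targets=[t.clipped(sizes) for t in bundle.targets],
            control=bundle.control.clipped(sizes))

    # -- construction -----------------------------------------------------

    @classmethod
    def from_config(cls, config: RunConfig) -> "DimerEnrichmentModel":
        """Build the model from a validated configuration (file inputs)."""
        problems = config.validate()
        if problems:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))
        motifs: list[Motif] = []
        for path, fmt in config.motif_files:
            motifs.extend(parse_motifs(path, fmt, pseudocount=config.pseudocount))
        problems = config.validate(motif_ids=[m.id for m in motifs])
        if problems:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))
        strong, weak = [], []
        for decl in config.datasets:
            replicates = [read_bed(p, name=f"{decl.name}[{i}]", kind=decl.kind)
                          for i, p in enumerate(decl.bed_paths)]
            merged = merge_replicates(replicates, decl.name)
            (strong if decl.kind == "strong" else weak).append(merged)
        bundle = build_targets(strong, weak)
        return cls(config.genome, motifs, bundle, config)

    # -- scope ------------------------------------------------------------

    def motif_pairs(self) -> list[tuple[str, str]]:
        """Motif pairs to screen, per the configured scope (sorted ids)."""
        ids = sorted(self.motif_by_id)
        cfg = self.config
        if cfg.scope == "all-pairs":
            pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i:]]
        elif cfg.scope == "fixed-motif":
            pairs = sorted({tuple(sorted((f, m)))
                            for f in cfg.fixed_motifs for m in ids})
        else:  # fixed-pair
            pairs = sorted({tuple(sorted(p)) for p in cfg.fixed_pairs})
        return pairs

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "DimerResults":
        cfg = self.config
        control = self.bundle.control
        targets = self.bundle.targets
        background = background_frequencies(self.genome, control)
        thresholds = {m.id: calibrate_threshold(m, cfg.sensitivity, background)
                      for m in self.motifs}
        logger.info("scanning %d motifs over control (%d regions, %d bp)",
                    len(self.motifs), len(control), control.total_bp)
        hits_control = scan(self.genome, control, self.motifs, thresholds, background)
        hits_target = {t.name: scan(self.genome, t, self.motifs, thresholds, background)
                       for t in targets}

        pairs = self.motif_pairs()
        lengths = {m.id: m.length for m in self.motifs}

        def process_pair(pair: tuple[str, str]):
            id1, id2 = pair
            min_sp = (cfg.min_spacing if cfg.min_spacing is not None
                      else default_min_spacing(lengths[id1], lengths[id2]))
            complexes = enumerate_complexes(id1, id2, min_sp, cfg.max_spacing)
            ctrl_inst = pair_instances(hits_control[id1], hits_control[id2],
                                       id1, id2, min_sp, cfg.max_spacing)
            ctrl_counts = {c: len(v) for c, v in ctrl_inst.items()}
            ctrl_pair_count = sum(ctrl_counts.values())
            ctrl_pair_placements = 0
            spans = {}
            for c in complexes:
                spans[c] = c.span(lengths)
                if spans[c] > 0:
                    ctrl_pair_placements += possible_placements(
                        control, spans[c], c.is_self_rc)
            b12_pair = (ctrl_pair_count / ctrl_pair_placements
                        if ctrl_pair_placements > 0 else 0.0)
            pair_results: list[EnrichmentResult] = []
            n_hyp = len(complexes) * len(targets)
            for t in targets:
                tgt_inst = pair_instances(hits_target[t.name][id1],
                                          hits_target[t.name][id2],
                                          id1, id2, min_sp, cfg.max_spacing)
                tgt_pair_count = sum(len(v) for v in tgt_inst.values())
                tgt_pair_placements = sum(
                    possible_placements(t, spans[c], c.is_self_rc)
                    for c in complexes if spans[c] > 0)
                if tgt_pair_placements == 0 or b12_pair <= 0:
                    continue
                f12 = tgt_pair_count / tgt_pair_placements
                for c in complexes:
                    if spans[c] <= 0:
                        logger.warning("complex %s has non-positive span; excluded",
                                       c.signature)
                        continue
                    res = test_complex(
                        c, t, control, spans[c],
                        c12_target=len(tgt_inst.get(c, ())),
                        c12_control=ctrl_counts.get(c, 0),
                        f12=f12, b12_pair=b12_pair,
                        instances=tgt_inst.get(c, []),
                        target_name=t.name)
                    if res is not None:
                        pair_results.append(res)
            return pair, n_hyp, pair_results

        if cfg.threads > 1:
            with ThreadPoolExecutor(max_workers=cfg.threads) as pool:
                raw = list(pool.map(process_pair, pairs))
        else:
            raw = [process_pair(p) for p in pairs]
        raw.sort(key=lambda x: x[0])  # canonical merge order

        n_hypotheses = sum(n for _, n, _ in raw)
        all_results = [r for _, _, lst in raw for r in lst]
        for r in all_results:
            r.p_adj = bonferroni(r.p_raw, n_hypotheses)
        reported = [r for r in all_results if r.C12 >= cfg.min_support]
        all_p_raw = np.sort(np.array([r.p_raw for r in all_results]))

        significant = [r for r in reported if r.p_adj < cfg.significance_alpha]
        clusters = cluster_all(significant, self.genome, cfg.cluster_params)

        # free instance lists we no longer need
        for r in all_results:
            if r.C12 < cfg.min_support:
                r.instances = []

        return DimerResults(
            model=self, results=reported, all_results=all_results,
            significant=significant, clusters=clusters,
            n_hypotheses=n_hypotheses, all_p_raw=all_p_raw,
            thresholds=thresholds, background=background)


@dataclass
class DimerResults:
    """Fitted results: predictions, clusters, diagnostics, writers."""

    model: DimerEnrichmentModel
    results: list[EnrichmentResult]          # C12 >= min_support
    all_results: list[EnrichmentResult]      # every testable hypothesis
    significant: list[EnrichmentResult]      # reported and Bonferroni-significant
    clusters: list[DimerCluster]
    n_hypotheses: int
    all_p_raw: np.ndarray
    thresholds: dict
    background: np.ndarray
    _flex_cache: dict = field(default_factory=dict, repr=False)

    # -- tables -----------------------------------------------------------

    def predictions_df(self, significant_only: bool = False) -> pd.DataFrame:
        rows = []
        for r in (self.significant if significant_only else self.results):
            c = r.complex
            rows.append({
                "target": r.target_name, "complex": r.signature,
                "left_motif": c.left_id, "right_motif": c.right_id,
                "left_strand": c.left_strand, "right_strand": c.right_strand,
                "spacing": c.spacing,
                "C12": r.C12, "N12": r.N12, "E12": r.E12, "f12": r.f12,
                "b12_pair": r.b12_pair, "b12_complex": r.b12_complex,
                "p_raw": r.p_raw, "p_adj": r.p_adj,
                "cluster_id": r.cluster_id, "join_type": r.join_type,
            })
        df = pd.DataFrame(rows)
        if len(df):
            df = df.sort_values(["p_raw", "complex", "target"]).reset_index(drop=True)
        return df

    def clusters_df(self) -> pd.DataFrame:
        rows = [{
            "cluster_id": cl.cluster_id,
            "seed_complex": cl.seed.signature,
            "seed_target": cl.seed.target_name,
            "n_members": cl.size,
            "best_p_adj": cl.best_p_adj,
        } for cl in self.clusters]
        return pd.DataFrame(rows)

    def qq_table(self) -> pd.DataFrame:
        """Observed sorted p-values vs uniform quantiles over all hypotheses.

        The expected quantile for rank i among H tested hypotheses is
        i / (H + 1); hypotheses skipped as untestable keep their place in H
        but contribute no observed point.
        """
        n = self.all_p_raw.size
        expected = (np.arange(1, n + 1)) / (self.n_hypotheses + 1)
        return pd.DataFrame({"expected": expected, "observed": self.all_p_raw})

    def spacing_profiles(self) -> pd.DataFrame:
        """Best p_raw per (pair, orientation, dataset, spacing), for spacing plots."""
        rows = []
        for r in self.all_results:
            c = r.complex
            rows.append({
                "left_motif": c.left_id, "right_motif": c.right_id,
                "orientation": f"{c.left_strand}{c.right_strand}",
                "dataset": r.target_name, "spacing": c.spacing,
                "p_raw": r.p_raw,
            })
        df = pd.DataFrame(rows)
        if len(df):
            df = (df.groupby(["left_motif", "right_motif", "orientation",
                              "dataset", "spacing"], as_index=False)["p_raw"]
                  .min().sort_values(["left_motif", "right_motif", "orientation",
                                      "dataset", "spacing"]).reset_index(drop=True))
        return df

    # -- flexibility -------------------------------------------------------

    def spacing_groups(self) -> list[SpacingGroup]:
        trims = trims_for(self.model.motifs, self.model.config.ic_trim_cutoff)
        return group_predictions(self.significant, trims)

    def flexibility(self, filter_outliers: bool = False) -> FlexibilityStats:
        key = bool(filter_outliers)
        if key not in self._flex_cache:
            groups = self.spacing_groups()
            if filter_outliers:
                groups, removed = iqr_outlier_filter(groups)
                if removed:
                    logger.info("flexibility: %d outlier group(s) removed", len(removed))
            self._flex_cache[key] = flexibility_stats(groups)
        return self._flex_cache[key]

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Dimer enrichment results",
            "=" * 64,
            f"motifs: {len(self.model.motifs)}   targets: "
            f"{len(self.model.bundle.targets)}   hypotheses: {self.n_hypotheses}",
            f"tested (reported, C12 >= {cfg.min_support}): {len(self.results)}   "
            f"significant (p_adj < {cfg.significance_alpha:g}): {len(self.significant)}",
            f"predicted dimers (clusters): {len(self.clusters)}",
            "",
        ]
        top = self.predictions_df(significant_only=True).head(10)
        if len(top):
            lines.append("top predictions:")
            cols = ["target", "complex", "C12", "E12", "p_raw", "p_adj", "cluster_id"]
            lines.append(top[cols].to_string(
                index=False, float_format=lambda x: f"{x:.3g}"))
        else:
            lines.append("no significant predictions")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, out_dir: str, write_instances: bool = True) -> None:
        """Write predictions/clusters/QQ/spacing/flexibility TSVs, cluster
        dimer PWMs (TRANSFAC format), instance BEDs, and a config echo."""
        os.makedirs(out_dir, exist_ok=True)
        self.predictions_df().to_csv(
            os.path.join(out_dir, "predictions.tsv"), sep="\t", index=False)
        self.clusters_df().to_csv(
            os.path.join(out_dir, "clusters.tsv"), sep="\t", index=False)
        self.qq_table().to_csv(
            os.path.join(out_dir, "qq.tsv"), sep="\t", index=False)
        self.spacing_profiles().to_csv(
            os.path.join(out_dir, "spacing_profiles.tsv"), sep="\t", index=False)
        flex = self.flexibility()
        flex.table.to_csv(
            os.path.join(out_dir, "flexibility.tsv"), sep="\t", index=False)
        pwms = [cl.dimer_pwm for cl in self.clusters if cl.dimer_pwm is not None]
        if pwms:
            write_transfac(pwms, os.path.join(out_dir, "dimer_pwms.transfac"))
        if write_instances and self.significant:
            with open(os.path.join(out_dir, "instances.bed"), "w") as fh:
                for r in self.significant:
                    for inst in r.instances:
                        fh.write(f"{inst.chrom}\t{inst.span_start}\t{inst.span_end}"
                                 f"\t{r.signature}\t0\t{inst.arrangement_strand}\n")
        with open(os.path.join(out_dir, "run_config.yaml"), "w") as fh:
            fh.write(self.model.config.to_yaml())
        with open(os.path.join(out_dir, "summary.txt"), "w") as fh:
            fh.write(self.summary() + "\n")

    # -- plots ---------------------------------------------------------------

    def plot_spacing_profile(self, left_motif: str, right_motif: str,
                             orientation: str, dataset: str, ax=None):
        """-log10 p versus spacing for one pair/orientation/dataset; the
        overlap boundary (spacing 0) is marked."""
        import matplotlib.pyplot as plt

        df = self.spacing_profiles()
        sel = df[(df.left_motif == left_motif) & (df.right_motif == right_motif)
                 & (df.orientation == orientation) & (df.dataset == dataset)]
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(sel.spacing, -np.log10(sel.p_raw.clip(lower=1e-300)), "o-")
        ax.axvline(-0.5, color="red", lw=1)
        ax.set_xlabel("motif spacing (bp)")
        ax.set_ylabel("-log10 p")
        ax.set_title(f"{left_motif}/{right_motif} {orientation} in {dataset}")
        return ax

    def plot_qq(self, ax=None):
        import matplotlib.pyplot as plt

        qq = self.qq_table()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(-np.log10(qq.expected), -np.log10(qq.observed.clip(lower=1e-300)), ".")
        lim = max(1.0, -np.log10(1.0 / (self.n_hypotheses + 1)))
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        return ax
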