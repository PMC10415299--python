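"""End-to-end reproducible pipeline over the synthetic patient.

simulate -> normalize/segment -> purity (haplotype-BAF + grid consensus) ->
tumor-fraction filter -> absolute CN -> SCRATCH (autosomes and chrX) ->
congruence -> AR copy number / gain classification -> AR score ->
clonal-mutation overlap statistics, with every artifact written to the run
directory and a machine-readable summary JSON.  Identical config + seed give
an identical summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as cnio
from .genome import BinGrid, default_grid
from .simulate import (CloneTreeSim, simulate_clone_tree, simulate_binned_counts,
                       simulate_phased_snps, simulate_expression)
from .profiles import (BinnedProfile, normalize_counts, segment_profile,
                       segment_absolute, call_absolute_cn, ar_copy_number,
                       xq_gained_fraction, classify_ar_gain,
                       bin_gain_proportion, filter_by_tumor_fraction)
from .purity import (select_anchor_regions, correct_switch_errors,
                     estimate_purity_hapbaf, grid_fit_purity_ploidy,
                     consensus_purity, PurityEstimate)
from .scratch import build_transition_matrix, correlation_distance, scratch_cluster
from .congruence import compare_trees
from .ar_activity import ARSignature, filter_and_normalize, zscore_matrix, ar_score
from .clonality import pairwise_overlaps, overlap_by_cluster_test

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable pipeline configuration; seeds are mandatory and explicit."""

    seed: int = 1
    n_clusters: int = 3
    samples_per_cluster: int = 4
    n_truncal: int = 5
    n_cluster_events: int = 15
    n_private: int = 3
    purity_range: tuple[float, float] = (0.2, 0.9)
    depth_per_bin: float = 1700.0
    dispersion: float = 1700.0
    snp_depth: float = 30.0
    snp_density: float = 20.0
    switch_rate: float = 0.02
    merge_tol: float = 0.3
    merge_tol_cn: float = 0.5
    min_tf: float = 0.2
    linkage: str = "complete"
    correlation: str = "pearson"
    k_max: int = 8
    n_perm: int = 999
    expression_effect: float = 1.0
    expression_noise: float = 0.3
    signature_path: str | None = None

    def validate(self) -> None:
        if self.merge_tol <= 0 or not (0 <= self.min_tf <= 1):
            raise ValueError("threshold out of documented bounds")
        if self.linkage not in ("complete", "average", "ward"):
            raise ValueError("linkage must be complete/average/ward")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["purity_range"] = list(self.purity_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "purity_range" in d:
            d["purity_range"] = tuple(d["purity_range"])
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:12]


def run_pipeline(config: RunConfig, outdir, grid: BinGrid | None = None) -> dict:
    """Execute every stage on a simulated patient; returns the summary dict
    (also written to ``outdir/summary.json``)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    grid = grid or default_grid()

    # --- simulate ---------------------------------------------------------
    tree = simulate_clone_tree(
        config.n_clusters, config.samples_per_cluster, config.n_truncal,
        config.n_cluster_events, config.n_private, config.purity_range,
        seed=config.seed, grid=grid)
    (outdir / "truth.json").write_text(tree.to_json())
    counts = simulate_binned_counts(tree, grid, config.depth_per_bin,
                                    config.dispersion, seed=config.seed + 10)
    snps = simulate_phased_snps(tree, depth=config.snp_depth,
                                snp_density=config.snp_density,
                                switch_rate=config.switch_rate,
                                seed=config.seed + 20)
    sig = (ARSignature.from_tsv(config.signature_path)
           if config.signature_path else ARSignature.default())
    expr = simulate_expression(tree, sig, config.expression_effect,
                               config.expression_noise, seed=config.seed + 30)
    cnio.write_table(snps.counts, outdir / "snps.tsv")
    cnio.write_mutations(tree.mutation_sets, outdir / "mutations.tsv")
    cnio.write_table(expr, outdir / "expression.tsv", index=True)

    # --- segment ----------------------------------------------------------
    segs = {}
    for sid, c in counts.items():
        prof = normalize_counts(BinnedProfile(sid, grid, c))
        segs[sid] = segment_profile(prof, config.merge_tol)
    cnio.write_seg(list(segs.values()), outdir / "segments_ratio.tsv")

    # --- purity -----------------------------------------------------------
    # the "high-coverage" reference sample is picked automatically: try
    # candidates in descending grid-fit purity until one yields >= 3 anchors
    grid_fits = {sid: grid_fit_purity_ploidy(s) for sid, s in segs.items()}
    anchors, high_cov = [], None
    for cand in sorted(grid_fits, key=lambda sid: -grid_fits[sid][0]):
        hc_rho, hc_psi, _, _ = grid_fits[cand]
        hc_seg = call_absolute_cn(segs[cand], hc_rho, hc_psi)
        cand_anchors = select_anchor_regions(hc_seg, snps.counts[
            snps.counts["sample"] == cand], hc_rho, hc_psi)
        if len(cand_anchors) >= 3:
            anchors, high_cov = cand_anchors, cand
            break
    if high_cov is None:
        high_cov = max(grid_fits, key=lambda sid: grid_fits[sid][0])
        log.warning("no candidate sample yielded 3 anchors; haplotype-BAF "
                    "purity will be invalid for all samples")
    corrected, n_dropped = correct_switch_errors(snps.counts, high_cov)
    estimates: dict[str, PurityEstimate] = {}
    for sid in segs:
        rho_hb, per_anchor = estimate_purity_hapbaf(corrected, anchors, sid)
        rho_g, psi_g, _, degen = grid_fits[sid]
        rho_c, discordant = consensus_purity(rho_hb, rho_g)
        estimates[sid] = PurityEstimate(
            sample_id=sid, rho_hapbaf=rho_hb, rho_grid=rho_g,
            rho_consensus=rho_c, psi=psi_g, n_anchors_used=len(per_anchor),
            per_anchor=per_anchor, hapbaf_valid=rho_hb is not None,
            discordant=discordant, degenerate=degen)

    kept = filter_by_tumor_fraction(
        {sid: e.rho_consensus for sid, e in estimates.items()}, config.min_tf)
    log.info("retained %d/%d samples at tumor fraction >= %.2f",
             len(kept), len(segs), config.min_tf)

    # --- absolute CN + SCRATCH -------------------------------------------
    # transition points come from segmentation on the absolute-CN scale
    called = {}
    for sid in kept:
        prof = normalize_counts(BinnedProfile(sid, grid, counts[sid]))
        called[sid] = segment_absolute(prof, estimates[sid].rho_consensus,
                                       estimates[sid].psi, config.merge_tol_cn)
    profiles = list(called.values())
    cnio.write_seg(profiles, outdir / "segments_cn.tsv")

    tm_auto = build_transition_matrix(profiles, "autosomes")
    t_auto = scratch_cluster(correlation_distance(tm_auto, config.correlation),
                             tm_auto.sample_ids, config.linkage, config.k_max)
    tm_x = build_transition_matrix(profiles, "chrX")
    t_x = scratch_cluster(correlation_distance(tm_x, config.correlation),
                          tm_x.sample_ids, config.linkage, config.k_max)
    cnio.write_newick(t_auto, outdir / "scratch_autosomes.nwk")
    cnio.write_newick(t_x, outdir / "scratch_chrX.nwk")

    cong = compare_trees(t_auto, t_x, n_perm=config.n_perm, seed=config.seed + 40)

    # --- AR status --------------------------------------------------------
    ar = {}
    for sid, seg in called.items():
        cn = ar_copy_number(seg)
        xq = xq_gained_fraction(seg)
        ar[sid] = {"ar_cn": cn, "xq_gained_fraction": xq,
                   "ar_gain": classify_ar_gain(cn, xq)}
    gain_prop = bin_gain_proportion(profiles)

    # --- expression -------------------------------------------------------
    norm = filter_and_normalize(expr[kept] if set(kept) <= set(expr.columns)
                                else expr)
    scores = ar_score(zscore_matrix(norm), sig)

    # --- clonality --------------------------------------------------------
    muts = {sid: tree.mutation_sets[sid] for sid in kept}
    cluster_of = {sid: t_auto.labels[sid] for sid in kept}
    ov = pairwise_overlaps(muts, cluster_of)
    overlap_p = (overlap_by_cluster_test(ov["overlap"], ov["same_cluster"])
                 if ov["same_cluster"].nunique() == 2 else None)

    summary = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_samples": len(segs),
        "n_retained": len(kept),
        "purity": {sid: {"hapbaf": e.rho_hapbaf, "grid": e.rho_grid,
                         "consensus": e.rho_consensus, "psi": e.psi,
                         "discordant": e.discordant}
                   for sid, e in estimates.items()},
        "true_purity": tree.purity_of,
        "clusters": {sid: int(t_auto.labels[sid]) for sid in kept},
        "true_clusters": {sid: tree.cluster_of[sid] for sid in kept},
        "k_autosomes": t_auto.k,
        "silhouette_autosomes": t_auto.silhouette,
        "k_chrX": t_x.k,
        "congruence": {"bakers_gamma": cong.bakers_gamma,
                       "gamma_p": cong.gamma_p,
                       "mast_size": cong.mast_size,
                       "i_cong": cong.i_cong,
                       "icong_p": cong.icong_p,
                       "congruent": cong.congruent},
        "ar_status": ar,
        "ar_gain_fraction": float(np.mean([v["ar_gain"] for v in ar.values()])),
        "chrX_gain_proportion_max": float(gain_prop.max()),
        "ar_scores": {s: int(v) for s, v in scores.items()},
        "overlap_p": overlap_p,
        "n_dropped_phase_blocks": n_dropped,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                    sort_keys=True))
    return summary
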