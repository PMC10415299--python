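"""Synthetic multi-metastasis clone simulator.

Generates fully specified inputs with planted clonal structure: a clone tree
with truncal, cluster-specific and sample-private copy-number events on the
bin grid; per-sample purities; negative-binomial binned read counts; phased
heterozygous-SNP allele counts with germline switch errors; nested clonal
mutation sets; and AR-response expression shifted by AR copy number.

Every simulator is deterministic given its seed.  Copy-number event
boundaries are rejection-sampled so that no two events share a boundary bin,
which keeps the planted truth unambiguous for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import BinGrid, default_grid


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# planted-truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNEvent:
    """A copy-number change on one parental allele over a bin interval.

    ``start_bin``/``end_bin`` are chrom-local, half-open.  ``delta`` is the
    integer change applied to the ``allele`` ('A' or 'B') copy count.
    """

    chrom: str
    start_bin: int
    end_bin: int
    delta: int
    allele: str = "A"

    def __post_init__(self) -> None:
        if self.start_bin >= self.end_bin:
            raise SimulationError("event must satisfy start_bin < end_bin")
        if self.allele not in ("A", "B"):
            raise SimulationError("allele must be 'A' or 'B'")


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    cluster_id: int
    purity: float


@dataclass
class CloneTreeSim:
    """Planted truth for one synthetic patient.

    Truncal events appear in every sample, cluster events exactly in that
    cluster's samples, private events in a single sample.  Mutation id sets
    are nested the same way (truncal ids are a subset of every sample's set).
    """

    patient_id: str
    clusters: list[int]
    samples: list[SampleSpec]
    truncal_events: list[CNEvent]
    cluster_events: dict[int, list[CNEvent]]
    private_events: dict[str, list[CNEvent]]
    mutation_sets: dict[str, set[str]]
    seed: int
    grid: BinGrid = field(default_factory=default_grid)
    anchors: list[tuple[str, int, int]] = field(default_factory=list)
    ar_gained_clusters: list[int] = field(default_factory=list)
    # within-cluster subclone genealogy: events shared by a subset of a
    # cluster's samples (one entry per internal node of the genealogy)
    subclone_events: dict[tuple[str, ...], list[CNEvent]] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def cluster_of(self) -> dict[str, int]:
        return {s.sample_id: s.cluster_id for s in self.samples}

    @property
    def purity_of(self) -> dict[str, float]:
        return {s.sample_id: s.purity for s in self.samples}

    def events_for_sample(self, sample_id: str) -> list[CNEvent]:
        spec = next(s for s in self.samples if s.sample_id == sample_id)
        out = (list(self.truncal_events)
               + list(self.cluster_events.get(spec.cluster_id, []))
               + list(self.private_events.get(sample_id, [])))
        for members, evs in self.subclone_events.items():
            if sample_id in members:
                out.extend(evs)
        return out

    def allele_copies(self, sample_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-bin tumor copies of allele A and B for one sample's clone."""
        g = self.grid
        n_a = np.where(g.autosome_mask, 1, 1).astype(float)
        n_b = np.where(g.autosome_mask, 1, 0).astype(float)
        for ev in self.events_for_sample(sample_id):
            idx = g.global_bins(ev.chrom, ev.start_bin, ev.end_bin)
            (n_a if ev.allele == "A" else n_b)[idx] += ev.delta
        if (n_a < 0).any() or (n_b < 0).any():
            raise SimulationError(f"negative allele copy number in {sample_id}")
        return n_a, n_b

    def total_copies(self, sample_id: str) -> np.ndarray:
        n_a, n_b = self.allele_copies(sample_id)
        return n_a + n_b

    def median_autosomal_ploidy(self, sample_id: str) -> float:
        """Tumor ploidy, defined as the median autosomal bin copy number.

        This matches the median-normalization convention used for read
        counts, so expected normalized ratios and the absolute-CN transform
        are exact inverses of one another.
        """
        return float(np.median(self.total_copies(sample_id)[self.grid.autosome_mask]))

    def ar_copy_number(self, sample_id: str) -> float:
        return float(self.total_copies(sample_id)[self.grid.global_bins("chrX")[self.grid.ar_bin]])

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        d = {
            "patient_id": self.patient_id,
            "clusters": self.clusters,
            "samples": [asdict(s) for s in self.samples],
            "truncal_events": [asdict(e) for e in self.truncal_events],
            "cluster_events": {str(k): [asdict(e) for e in v]
                               for k, v in self.cluster_events.items()},
            "private_events": {k: [asdict(e) for e in v]
                               for k, v in self.private_events.items()},
            "mutation_sets": {k: sorted(v) for k, v in self.mutation_sets.items()},
            "subclone_events": {",".join(k): [asdict(e) for e in v]
                                for k, v in self.subclone_events.items()},
            "seed": self.seed,
            "anchors": [list(a) for a in self.anchors],
            "ar_gained_clusters": self.ar_gained_clusters,
            "grid": {"chrom_names": list(self.grid.chrom_names),
                     "chrom_bins": list(self.grid.chrom_bins),
                     "bin_width": self.grid.bin_width,
                     "ar_bin": self.grid.ar_bin,
                     "enhancer_bin": self.grid.enhancer_bin,
                     "xq_start_bin": self.grid.xq_start_bin},
        }
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CloneTreeSim":
        d = json.loads(text)
        g = d["grid"]
        grid = BinGrid(tuple(g["chrom_names"]), tuple(g["chrom_bins"]), g["bin_width"],
                       g["ar_bin"], g["enhancer_bin"], g["xq_start_bin"])
        return cls(
            patient_id=d["patient_id"],
            clusters=list(d["clusters"]),
            samples=[SampleSpec(**s) for s in d["samples"]],
            truncal_events=[CNEvent(**e) for e in d["truncal_events"]],
            cluster_events={int(k): [CNEvent(**e) for e in v]
                            for k, v in d["cluster_events"].items()},
            private_events={k: [CNEvent(**e) for e in v]
                            for k, v in d["private_events"].items()},
            mutation_sets={k: set(v) for k, v in d["mutation_sets"].items()},
            seed=d["seed"],
            grid=grid,
            anchors=[tuple(a) for a in d["anchors"]],
            ar_gained_clusters=list(d["ar_gained_clusters"]),
            subclone_events={tuple(k.split(",")): [CNEvent(**e) for e in v]
                             for k, v in d.get("subclone_events", {}).items()},
        )


# ---------------------------------------------------------------------------
# clone-tree simulation
# ---------------------------------------------------------------------------

def _draw_event(rng: np.random.Generator, grid: BinGrid, chroms: list[str],
                used_boundaries: set[tuple[str, int]],
                min_bins: int, max_bins: int, delta_choices: tuple[int, ...],
                carriers_alleles: list[tuple[np.ndarray, np.ndarray]],
                fixed_allele: str | None = None,
                forbidden: list[tuple[str, int, int]] = (),
                max_tries: int = 2000) -> CNEvent:
    """Rejection-sample one event whose boundary bins are unused, which avoids
    the forbidden intervals, and which keeps allele copy numbers non-negative
    in every carrying sample."""
    for _ in range(max_tries):
        chrom = chroms[rng.integers(len(chroms))]
        n = grid.n_chrom_bins(chrom)
        length = int(rng.integers(min_bins, min(max_bins, n - 1) + 1))
        start = int(rng.integers(0, n - length + 1))
        end = start + length
        if (chrom, start) in used_boundaries or (chrom, end) in used_boundaries:
            continue
        if any(c == chrom and start < e and s < end for c, s, e in forbidden):
            continue
        delta = int(delta_choices[rng.integers(len(delta_choices))])
        if fixed_allele is not None:
            allele = fixed_allele
        else:
            allele = "A" if chrom == "chrX" else ("A", "B")[rng.integers(2)]
        idx = grid.global_bins(chrom, start, end)
        ok = True
        if delta < 0:
            for n_a, n_b in carriers_alleles:
                arr = n_a if allele == "A" else n_b
                if (arr[idx] + delta < 0).any():
                    ok = False
                    break
        if not ok:
            continue
        ev = CNEvent(chrom, start, end, delta, allele)
        for n_a, n_b in carriers_alleles:
            (n_a if allele == "A" else n_b)[idx] += delta
        used_boundaries.add((chrom, start))
        used_boundaries.add((chrom, end))
        return ev
    raise SimulationError("could not place event without boundary collision")


def simulate_clone_tree(n_clusters: int, samples_per_cluster: int,
                        n_truncal: int = 5, n_cluster: int = 15, n_private: int = 3,
                        purity_range: tuple[float, float] = (0.2, 0.9),
                        seed: int = 0, *,
                        grid: BinGrid | None = None,
                        patient_id: str = "SIM01",
                        n_anchor_loh: int = 3,
                        n_cluster_chrx: int = 4,
                        n_subclonal: int = 4,
                        n_branch: int = 4,
                        plant_ar_gain: bool = True,
                        ar_gain_range: tuple[int, int] = (5, 20),
                        n_truncal_mut: int = 50, n_cluster_mut: int = 20,
                        n_private_mut: int = 5) -> CloneTreeSim:
    """Plant a clone tree with truncal / cluster / private copy-number events.

    Besides the generic ``n_truncal`` truncal events, ``n_anchor_loh`` long
    truncal LOH deletions are planted on distinct autosomes; these serve as
    purity anchor regions downstream.  Alternating clusters (starting with
    the first) additionally receive a focal high-level AR amplification on
    Xq, plus ``n_cluster_chrx`` single-copy chrX events, so that chromosome X
    architecture tracks the autosomal cluster structure.

    Within each cluster a random binary subclone genealogy over its samples
    is planted: each internal node of the genealogy (a subset of the
    cluster's samples) shares ``n_subclonal`` events, split between an
    autosome and chrX.  The clusters themselves are likewise joined in a
    random binary order with ``n_branch`` events per join shared by the
    sister clusters (clusters are clades of one patient clone tree), so that
    sample relatedness is hierarchical on both autosomes and chromosome X —
    the structure that makes autosome/chrX dendrogram congruence testable.
    """
    if n_clusters < 1 or samples_per_cluster < 1:
        raise SimulationError("need at least one cluster and one sample per cluster")
    if min(n_truncal, n_cluster, n_private) < 0:
        raise SimulationError("event counts must be non-negative")
    lo, hi = purity_range
    if not (0 < lo <= hi <= 1):
        raise SimulationError("purity_range must lie inside (0, 1]")
    grid = grid or default_grid()
    autosomes = [c for c in grid.chrom_names if c != "chrX"]
    if not autosomes:
        raise SimulationError("genome model needs at least one autosome")
    rng = np.random.default_rng(seed)

    clusters = list(range(1, n_clusters + 1))
    samples: list[SampleSpec] = []
    for cl in clusters:
        for j in range(samples_per_cluster):
            sid = f"{patient_id}_{cl}_{j + 1}"
            samples.append(SampleSpec(sid, cl, float(rng.uniform(lo, hi))))

    # allele-copy state per sample, updated as events are planted
    state = {s.sample_id: [np.where(grid.autosome_mask, 1.0, 1.0),
                           np.where(grid.autosome_mask, 1.0, 0.0)]
             for s in samples}
    used: set[tuple[str, int]] = set()
    all_states = [tuple(state[s.sample_id]) for s in samples]

    truncal: list[CNEvent] = []
    # long LOH deletions on distinct autosomes: the purity anchors
    anchors: list[tuple[str, int, int]] = []
    anchor_chroms = list(rng.permutation(autosomes))
    for i in range(n_anchor_loh):
        chrom = anchor_chroms[i % len(anchor_chroms)]
        ev = _draw_event(rng, grid, [chrom], used, min_bins=30, max_bins=60,
                         delta_choices=(-1,), carriers_alleles=all_states,
                         fixed_allele="B")
        truncal.append(ev)
        anchors.append((ev.chrom, ev.start_bin, ev.end_bin))
    for i in range(n_truncal):
        truncal.append(_draw_event(rng, grid, autosomes, used, 5, 40, (1, -1),
                                   all_states, forbidden=anchors))

    cluster_events: dict[int, list[CNEvent]] = {}
    ar_gained: list[int] = []
    for ci, cl in enumerate(clusters):
        members = [tuple(state[s.sample_id]) for s in samples if s.cluster_id == cl]
        evs: list[CNEvent] = []
        for _ in range(n_cluster):
            evs.append(_draw_event(rng, grid, autosomes, used, 5, 40, (1, -1),
                                   members, forbidden=anchors))
        if "chrX" in grid.chrom_names:
            for _ in range(n_cluster_chrx):
                evs.append(_draw_event(rng, grid, ["chrX"], used, 5, 30, (1, -1), members))
            if plant_ar_gain and ci % 2 == 0:
                evs.append(_plant_ar_gain(rng, grid, used, ar_gain_range, members))
                ar_gained.append(cl)
        cluster_events[cl] = evs

    # within-cluster subclone genealogy: random sequential joins; each
    # internal node (proper subset of >= 2 samples) carries shared events
    subclone_events: dict[tuple[str, ...], list[CNEvent]] = {}
    if n_subclonal > 0:
        for cl in clusters:
            member_ids = [s.sample_id for s in samples if s.cluster_id == cl]
            groups = [(sid,) for sid in member_ids]
            while len(groups) > 2:
                i, j = sorted(rng.choice(len(groups), size=2, replace=False))
                merged = tuple(sorted(groups[i] + groups[j]))
                groups = [g for k, g in enumerate(groups) if k not in (i, j)]
                groups.append(merged)
                carriers = [tuple(state[sid]) for sid in merged]
                evs = []
                for e in range(n_subclonal):
                    if e % 2 == 1 and "chrX" in grid.chrom_names:
                        # subclones differ substantially in chrX architecture
                        # (moderate-amplitude gains/losses around the X events)
                        evs.append(_draw_event(rng, grid, ["chrX"], used, 3, 20,
                                               (-2, -1, 1, 2, 3), carriers,
                                               forbidden=anchors))
                    else:
                        evs.append(_draw_event(rng, grid, autosomes, used, 3, 20,
                                               (1, -1), carriers,
                                               forbidden=anchors))
                subclone_events[merged] = evs

    # cluster-level clone tree: clusters joined in random binary order, each
    # join sharing n_branch events across the sister clusters' samples
    if n_branch > 0 and len(clusters) > 2:
        groups = [tuple(s.sample_id for s in samples if s.cluster_id == cl)
                  for cl in clusters]
        while len(groups) > 2:
            i, j = sorted(rng.choice(len(groups), size=2, replace=False))
            merged = tuple(sorted(groups[i] + groups[j]))
            groups = [g for k, g in enumerate(groups) if k not in (i, j)]
            groups.append(merged)
            carriers = [tuple(state[sid]) for sid in merged]
            evs = []
            for e in range(n_branch):
                pool = ["chrX"] if (e % 2 == 1 and "chrX" in grid.chrom_names) \
                    else autosomes
                evs.append(_draw_event(rng, grid, pool, used, 5, 30, (1, -1),
                                       carriers, forbidden=anchors))
            subclone_events[merged] = evs

    private_events: dict[str, list[CNEvent]] = {}
    chroms_all = list(grid.chrom_names)
    for s in samples:
        evs = []
        for _ in range(n_private):
            evs.append(_draw_event(rng, grid, chroms_all, used, 3, 20, (1, -1),
                                   [tuple(state[s.sample_id])], forbidden=anchors))
        private_events[s.sample_id] = evs

    tree = CloneTreeSim(patient_id=patient_id, clusters=clusters, samples=samples,
                        truncal_events=truncal, cluster_events=cluster_events,
                        private_events=private_events, mutation_sets={},
                        seed=seed, grid=grid, anchors=anchors,
                        ar_gained_clusters=ar_gained,
                        subclone_events=subclone_events)
    for s in samples:
        tree.allele_copies(s.sample_id)
    tree.mutation_sets = simulate_clonal_mutations(
        tree, n_truncal_mut, n_cluster_mut, n_private_mut, seed=seed + 1)
    return tree


def _plant_ar_gain(rng: np.random.Generator, grid: BinGrid,
                   used: set[tuple[str, int]], amp_range: tuple[int, int],
                   carriers: list) -> CNEvent:
    """Focal high-level amplification covering the AR (and enhancer) bin,
    contained in Xq and spanning well under 80% of it."""
    nx = grid.n_chrom_bins("chrX")
    xq_len = nx - grid.xq_start_bin
    for _ in range(2000):
        length = int(rng.integers(2, max(3, xq_len // 4)))
        lo = max(grid.xq_start_bin, grid.enhancer_bin - length + 1)
        hi = min(grid.enhancer_bin, nx - length)
        if hi < lo:
            continue
        start = int(rng.integers(lo, hi + 1))
        end = start + length
        if end <= grid.ar_bin or start > grid.enhancer_bin:
            continue
        if ("chrX", start) in used or ("chrX", end) in used:
            continue
        if end - start >= 0.8 * xq_len:
            continue
        delta = int(rng.integers(amp_range[0], amp_range[1] + 1))
        ev = CNEvent("chrX", start, end, delta, "A")
        idx = grid.global_bins("chrX", start, end)
        for n_a, _ in carriers:
            n_a[idx] += delta
        used.add(("chrX", start))
        used.add(("chrX", end))
        return ev
    raise SimulationError("could not place AR amplification")


# ---------------------------------------------------------------------------
# binned read counts
# ---------------------------------------------------------------------------

def expected_ratio(tree: CloneTreeSim, sample_id: str) -> np.ndarray:
    """Closed-form expected normalized read-count ratio per bin.

    r = (rho*c_t + c_n*(1-rho)) / D with D = rho*psi_t + 2*(1-rho), where
    psi_t is the sample's median autosomal tumor copy number.  The median
    autosomal bin therefore has expected ratio ~1, matching median
    normalization of raw counts.
    """
    spec = next(s for s in tree.samples if s.sample_id == sample_id)
    rho = spec.purity
    c_t = tree.total_copies(sample_id)
    c_n = tree.grid.normal_copies
    psi = tree.median_autosomal_ploidy(sample_id)
    d = rho * psi + 2.0 * (1.0 - rho)
    return (rho * c_t + c_n * (1.0 - rho)) / d


def simulate_binned_counts(tree: CloneTreeSim, bin_grid: BinGrid | None = None,
                           depth_per_bin: float = 1700.0, dispersion: float = 1700.0,
                           seed: int = 0) -> dict[str, "np.ndarray"]:
    """Negative-binomial bin counts per sample.

    Counts are drawn with mean ``depth_per_bin * r`` (``r`` the expected
    normalized ratio) and gamma-Poisson dispersion ``k``; ``k = inf`` gives
    the Poisson limit.  Returns ``{sample_id: counts}``.
    """
    grid = bin_grid or tree.grid
    if grid is not tree.grid and grid != tree.grid:
        raise SimulationError("bin grid does not match the clone tree's grid")
    if depth_per_bin <= 0 or dispersion <= 0:
        raise SimulationError("depth_per_bin and dispersion must be positive")
    rng = np.random.default_rng(seed)
    out = {}
    for s in tree.samples:
        mu = depth_per_bin * expected_ratio(tree, s.sample_id)
        if np.isinf(dispersion):
            counts = rng.poisson(mu)
        else:
            lam = rng.gamma(shape=dispersion, scale=mu / dispersion)
            counts = rng.poisson(lam)
        out[s.sample_id] = counts.astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# phased SNPs
# ---------------------------------------------------------------------------

@dataclass
class PhasedSNPTable:
    """Long-format phased SNP allele counts plus hidden phasing truth.

    ``counts`` columns: sample, chrom, pos, anchor_id, a_count, b_count —
    reads supporting the allele the (error-prone) phasing labels haplotype A
    vs B.  ``truth`` columns: chrom, pos, anchor_id, orient (+1 if the
    reported A label matches the true haplotype A, -1 if switched).
    """

    counts: pd.DataFrame
    truth: pd.DataFrame


def snp_allele_fraction(rho: float, n_a: float, n_b: float, c_n: float = 2.0) -> float:
    """Expected haplotype-A allele fraction at a het SNP inside a region with
    allele-specific tumor copies (n_a, n_b)."""
    return (rho * n_a + (1.0 - rho) * c_n / 2.0) / (rho * (n_a + n_b) + c_n * (1.0 - rho))


def simulate_phased_snps(tree: CloneTreeSim,
                         anchor_regions: list[tuple[str, int, int]] | None = None,
                         snp_density: float = 20.0, depth: float = 30.0,
                         switch_rate: float = 0.02, seed: int = 0) -> PhasedSNPTable:
    """Phased het-SNP counts in anchor regions for every sample.

    SNP positions are uniform within each anchor at ``snp_density`` per Mb.
    The germline phasing carries a Markov switch process: the reported
    haplotype orientation flips between consecutive SNPs with probability
    ``switch_rate`` (shared by all samples — phasing is a germline property).
    Per sample, read depth is Poisson(``depth``) and the haplotype-A read
    count binomial around the allele fraction implied by the local event
    state and purity.
    """
    if not 0 <= switch_rate < 0.5:
        raise SimulationError("switch_rate must lie in [0, 0.5)")
    grid = tree.grid
    regions = anchor_regions if anchor_regions is not None else tree.anchors
    if not regions:
        raise SimulationError("no anchor regions to simulate SNPs in")
    rng = np.random.default_rng(seed)

    truth_rows, count_rows = [], []
    alleles = {s.sample_id: tree.allele_copies(s.sample_id) for s in tree.samples}
    for aid, (chrom, start_bin, end_bin) in enumerate(regions):
        if chrom not in grid.chrom_names or end_bin > grid.n_chrom_bins(chrom):
            raise SimulationError(f"anchor {aid} off the genome model")
        mb = (end_bin - start_bin) * grid.bin_width / 1e6
        n_snps = max(1, int(round(snp_density * mb)))
        pos = np.sort(rng.integers(start_bin * grid.bin_width,
                                   end_bin * grid.bin_width, size=n_snps))
        flips = rng.random(n_snps) < switch_rate
        orient = np.where(np.cumsum(flips) % 2 == 0, 1, -1)
        local_bin = pos // grid.bin_width
        gbin = grid.offsets[chrom] + local_bin
        c_n = 2.0 if chrom != "chrX" else 1.0
        for p, o in zip(pos, orient):
            truth_rows.append((chrom, int(p), aid, int(o)))
        for s in tree.samples:
            n_a, n_b = alleles[s.sample_id]
            p_a = np.array([snp_allele_fraction(s.purity, n_a[g], n_b[g], c_n)
                            for g in gbin])
            dp = rng.poisson(depth, size=n_snps)
            true_a = rng.binomial(dp, p_a)
            rep_a = np.where(orient == 1, true_a, dp - true_a)
            for p, d_i, a_i in zip(pos, dp, rep_a):
                count_rows.append((s.sample_id, chrom, int(p), aid,
                                   int(a_i), int(d_i - a_i)))
    counts = pd.DataFrame(count_rows,
                          columns=["sample", "chrom", "pos", "anchor_id",
                                   "a_count", "b_count"])
    truth = pd.DataFrame(truth_rows, columns=["chrom", "pos", "anchor_id", "orient"])
    return PhasedSNPTable(counts=counts, truth=truth)


# ---------------------------------------------------------------------------
# clonal mutations
# ---------------------------------------------------------------------------

def simulate_clonal_mutations(tree: CloneTreeSim, n_truncal_mut: int = 50,
                              n_cluster_mut: int = 20, n_private_mut: int = 5,
                              seed: int = 0) -> dict[str, set[str]]:
    """Nested clonal mutation-id sets: truncal ids in every sample, cluster
    ids exactly within the cluster, private ids in one sample."""
    if min(n_truncal_mut, n_cluster_mut, n_private_mut) < 0:
        raise SimulationError("mutation counts must be non-negative")
    truncal = {f"T{i:04d}" for i in range(n_truncal_mut)}
    out: dict[str, set[str]] = {}
    for s in tree.samples:
        ids = set(truncal)
        ids |= {f"C{s.cluster_id}_{i:04d}" for i in range(n_cluster_mut)}
        ids |= {f"P_{s.sample_id}_{i:04d}" for i in range(n_private_mut)}
        out[s.sample_id] = ids
    return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(tree: CloneTreeSim, signature, effect_size: float = 1.0,
                        noise_sd: float = 0.3, seed: int = 0, *,
                        baseline_log2: float = 8.0,
                        n_background: int = 200) -> pd.DataFrame:
    """Gene x sample counts with AR-response genes shifted by AR copy number.

    Signature up-genes gain ``effect_size * log2(AR CN)`` on the log2 scale
    (down-genes lose it); Gaussian log-scale noise of ``noise_sd`` is added,
    then values are exponentiated and rounded to counts.  Background genes
    are unshifted.
    """
    genes = signature.directions  # dict gene -> 'up'|'down'
    if not genes:
        raise SimulationError("signature is empty")
    rng = np.random.default_rng(seed)
    names = list(genes) + [f"BG{i:04d}" for i in range(n_background)]
    mat = np.empty((len(names), len(tree.samples)))
    for j, s in enumerate(tree.samples):
        ar_cn = max(tree.ar_copy_number(s.sample_id), 0.5)
        shift = effect_size * np.log2(ar_cn)
        for i, g in enumerate(names):
            mu = baseline_log2
            if g in genes:
                mu += shift if genes[g] == "up" else -shift
            mat[i, j] = mu
    mat += rng.normal(0.0, noise_sd, size=mat.shape)
    counts = np.rint(np.exp2(mat)).astype(np.int64)
    return pd.DataFrame(counts, index=names, columns=tree.sample_ids)
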