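"""Synthetic two-cell-line BioID screens with planted ground truth.

The generator emulates the design of a proximity-labeling screen scored with
SAINT: a panel of baits assayed in biological replicates in two cell lines,
alongside three control purifications (empty BirA*-Flag vector, soluble
BirA*-Flag-eGFP, and membrane-targeted BirA*-Flag-eGFP-CAAX).  Spectral
counts are negative-binomially distributed (overdispersion parameterised as
the NB size); background detection is frequency-graded across preys; a small
set of membrane-resident preys is strongly elevated in the CAAX control and
mildly elevated in every bait; and SAINT average probabilities are simulated
from Beta distributions rather than recomputed, since probabilistic scoring
of the raw counts is upstream of this package.

Two classes of "sticky" background are planted in addition to ordinary
background, mirroring what real screens contain: frequent-flyer preys that
are seen across most purifications (including the controls) with moderate
counts yet high simulated probabilities — the class that motivates
spectral-count and control-ratio filters — and named contaminants (keratins,
endogenous biotin-dependent carboxylases) that match the shipped blocklist.

The planted spectral-count separation between true edges and probability-
passing background is computed analytically from the generating NB
distributions (Youden-optimal threshold), so recovery tests compare a sample
estimate against an analytic plant, never against another sample estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_formats import InteractionTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_screen",
    "benchmark_recovery",
    "planted_avg_spec_threshold",
    "simulate_wds_matrix",
    "simulate_marker_atlas",
    "simulate_localized_baits",
    "simulate_replicate_matrix",
]

#: Named contaminants planted in every purification; all are on the default
#: filtering blocklist.
BLOCKLIST_CONTAMINANTS = ("PC", "PCCA", "PCCB", "MCCC1", "KRT1", "KRT9")

_CONTROL_IDS = {"empty_vector": "CTRL_EMPTY", "gfp": "CTRL_GFP", "caax": "CTRL_CAAX"}


@dataclass
class SimConfig:
    """Study conditions for a simulated screen.

    Defaults emulate a 28-bait panel screened in duplicate in two cell lines
    with ~2% planted true preys per bait, strong true-edge counts (NB mean
    25) over a sparse low-count background (NB mean 3).
    """

    n_baits: int = 28
    n_preys: int = 2000
    frac_true_per_bait: float = 0.02
    shared_edge_prob: float = 0.4
    mu_true: float = 25.0
    mu_bg: float = 3.0
    dispersion: float = 4.0  # negative-binomial size; larger = less overdispersed
    detect_prob_bg: float = 0.15  # mean per-prey background detection probability
    n_membrane_preys: int = 100
    caax_boost: float = 3.0  # CAAX-control count multiplier for membrane preys
    membrane_bait_boost: float = 1.5  # mild elevation of membrane preys in all baits
    n_replicates: int = 2
    avgp_true_beta: tuple[float, float] = (50.0, 1.0)
    avgp_bg_beta: tuple[float, float] = (1.0, 20.0)
    # frequent-flyer sticky background: each such prey has a characteristic
    # abundance shared across purifications (controls included), and the
    # simulated SAINT probability is only fooled on a fraction of its records
    n_frequent_preys: int = 50
    mu_frequent: float = 6.0
    detect_prob_frequent: float = 0.9
    frequent_highp_prob: float = 0.15
    #: fraction of ordinary detected background records whose simulated SAINT
    #: probability is nevertheless high — the false-positive class that makes
    #: secondary spectral-count filtering necessary at all
    bg_highp_prob: float = 0.03
    include_blocklist_contaminants: bool = True
    cell_lines: tuple[str, str] = ("HEK293", "HeLa")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_true_per_bait", "shared_edge_prob", "detect_prob_bg",
                     "detect_prob_frequent"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must be in [0, 1]")
        for name in ("mu_true", "mu_bg", "mu_frequent", "dispersion"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.frac_true_per_bait * self.n_preys < 1:
            raise ValidationError(
                "infeasible config: frac_true_per_bait x n_preys < 1 true prey per bait"
            )


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated screen."""

    true_edges: dict[str, set[tuple[str, str]]]  # cell line -> {(bait, prey)}
    membrane_preys: set[str]
    frequent_preys: set[str] = field(default_factory=set)
    planted_avg_spec_threshold: float = 0.0


#: Gamma shape of the per-prey characteristic abundance of sticky background.
_FREQ_LAMBDA_SHAPE = 4.0


#: Gamma shape of the per-prey characteristic abundance of sticky background.
_FREQ_LAMBDA_SHAPE = 4.0


def planted_avg_spec_threshold(cfg: SimConfig) -> float:
    """Youden-optimal AvgSpec separating true edges from probability-passing
    background, computed analytically from the generating distributions.

    The spectral-count sum over r replicates of an NB(size s, mean m) record
    is NB(size r*s, mean r*m).  Positives mix ordinary and membrane-boosted
    true edges; negatives mix ordinary background, membrane background and
    the Gamma-abundance sticky class, weighted by each class's expected
    number of probability-passing records.  Both classes are truncated at
    zero (all-zero records are never observed).  The optimum lies on the
    AvgSpec lattice k/r.
    """
    r = cfg.n_replicates
    size_sum = r * cfg.dispersion
    hi = int(
        stats.nbinom.ppf(
            0.9999,
            size_sum,
            size_sum / (size_sum + r * cfg.mu_true * cfg.membrane_bait_boost),
        )
    ) + 1
    ks = np.arange(0, hi + 1)

    def _pmf(mu: float) -> np.ndarray:
        p = size_sum / (size_sum + r * mu)
        return stats.nbinom.pmf(ks, size_sum, p)

    def _gamma_mix_pmf(mean: float) -> np.ndarray:
        shape = _FREQ_LAMBDA_SHAPE
        lam_dist = stats.gamma(shape, scale=mean / shape)
        lam = np.linspace(lam_dist.ppf(1e-5), lam_dist.ppf(1 - 1e-5), 400)
        w = lam_dist.pdf(lam)
        w /= w.sum()
        p = size_sum / (size_sum + r * lam)
        return (stats.nbinom.pmf(ks[:, None], size_sum, p[None, :]) * w).sum(axis=1)

    memb_frac = min(cfg.n_membrane_preys, cfg.n_preys) / cfg.n_preys
    pmf_pos = (1 - memb_frac) * _pmf(cfg.mu_true) + memb_frac * _pmf(
        cfg.mu_true * cfg.membrane_bait_boost
    )

    # expected probability-passing records per bait for each background class
    w_bg = cfg.n_preys * (1 - memb_frac) * cfg.detect_prob_bg * cfg.bg_highp_prob
    w_memb = cfg.n_preys * memb_frac * cfg.detect_prob_bg * cfg.bg_highp_prob
    w_freq = cfg.n_frequent_preys * cfg.detect_prob_frequent * cfg.frequent_highp_prob
    w_contam = (
        float(len(BLOCKLIST_CONTAMINANTS)) if cfg.include_blocklist_contaminants else 0.0
    )
    total = w_bg + w_memb + w_freq + w_contam
    pmf_neg = (
        w_bg * _pmf(cfg.mu_bg)
        + w_memb * _pmf(cfg.mu_bg * cfg.membrane_bait_boost)
        + w_freq * _gamma_mix_pmf(cfg.mu_frequent)
        + w_contam * _gamma_mix_pmf(4.0 * cfg.mu_bg)
    ) / total

    # zero-truncate: an all-zero record never enters the table
    pmf_pos[0] = pmf_neg[0] = 0.0
    cdf_pos = np.cumsum(pmf_pos / pmf_pos.sum())
    cdf_neg = np.cumsum(pmf_neg / pmf_neg.sum())

    j = cdf_neg[:-1] - cdf_pos[:-1]  # J at threshold (k+1)/r
    return float(ks[1:][int(np.argmax(j))] / r)


def _nb_counts(rng: np.random.Generator, mu: float, size: float, shape) -> np.ndarray:
    p = size / (size + mu)
    return rng.negative_binomial(size, p, size=shape)


def simulate_screen(cfg: SimConfig) -> tuple[InteractionTable, SimTruth]:
    """Generate a SAINT-style table (both cell lines, controls included).

    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    baits = [f"BAIT{i + 1:02d}" for i in range(cfg.n_baits)]
    preys = [f"PREY{i + 1:04d}" for i in range(cfg.n_preys)]
    membrane = set(rng.choice(preys, size=min(cfg.n_membrane_preys, cfg.n_preys),
                              replace=False))
    frequent = [f"FREQ{i + 1:02d}" for i in range(cfg.n_frequent_preys)]
    contaminants = list(BLOCKLIST_CONTAMINANTS) if cfg.include_blocklist_contaminants else []

    # Planted true edges: a master prey set per bait; each edge lands in both
    # cell lines with shared_edge_prob, else in one line at random.
    n_true = int(round(cfg.frac_true_per_bait * cfg.n_preys))
    line_a, line_b = cfg.cell_lines
    true_edges: dict[str, set[tuple[str, str]]] = {line_a: set(), line_b: set()}
    for bait in baits:
        chosen = rng.choice(preys, size=n_true, replace=False)
        for prey in chosen:
            if rng.random() < cfg.shared_edge_prob:
                true_edges[line_a].add((bait, prey))
                true_edges[line_b].add((bait, prey))
            elif rng.random() < 0.5:
                true_edges[line_a].add((bait, prey))
            else:
                true_edges[line_b].add((bait, prey))

    # Frequency-graded background: per-prey detection probability drawn from
    # a Beta with the configured mean.
    d = cfg.detect_prob_bg
    bg_detect = (
        rng.beta(2.0, 2.0 * (1.0 - d) / d, size=cfg.n_preys)
        if 0 < d < 1
        else np.full(cfg.n_preys, d)
    )
    bg_detect_by_prey = dict(zip(preys, bg_detect))

    r = cfg.n_replicates
    rows: list[tuple] = []

    def _emit(bait, prey, line, counts, avgp, is_control):
        counts = tuple(int(c) for c in counts)
        if sum(counts) == 0:
            return
        rows.append((bait, prey, line, float(np.mean(counts)), float(avgp),
                     counts, is_control))

    def _avgp(true: bool) -> float:
        a, b = cfg.avgp_true_beta if true else cfg.avgp_bg_beta
        return min(rng.beta(a, b), 1.0)

    all_purifications = [(b, False) for b in baits] + [
        (_CONTROL_IDS["empty_vector"], True),
        (_CONTROL_IDS["gfp"], True),
        (_CONTROL_IDS["caax"], True),
    ]
    shape = _FREQ_LAMBDA_SHAPE
    for line in cfg.cell_lines:
        edges = true_edges[line]
        # characteristic per-line abundance of each sticky prey, shared across
        # purifications so its control ratio sits near 1
        freq_lambda = dict(
            zip(frequent, rng.gamma(shape, cfg.mu_frequent / shape, size=len(frequent)))
        )
        contam_lambda = dict(
            zip(contaminants,
                rng.gamma(shape, 4.0 * cfg.mu_bg / shape, size=len(contaminants)))
        )
        for bait, is_control in all_purifications:
            is_caax = bait == _CONTROL_IDS["caax"]
            # ordinary and membrane preys
            for prey in preys:
                memb = prey in membrane
                if (bait, prey) in edges:
                    mu = cfg.mu_true * (cfg.membrane_bait_boost if memb else 1.0)
                    counts = _nb_counts(rng, mu, cfg.dispersion, r)
                    _emit(bait, prey, line, counts, _avgp(True), is_control)
                elif is_caax and memb:
                    if rng.random() < 0.9:
                        counts = _nb_counts(rng, cfg.mu_bg * cfg.caax_boost,
                                            cfg.dispersion, r)
                        _emit(bait, prey, line, counts, 0.0, True)
                elif rng.random() < bg_detect_by_prey[prey]:
                    mu = cfg.mu_bg * (cfg.membrane_bait_boost if memb else 1.0)
                    counts = _nb_counts(rng, mu, cfg.dispersion, r)
                    fooled = rng.random() < cfg.bg_highp_prob
                    avgp = 0.0 if is_control else _avgp(fooled)
                    _emit(bait, prey, line, counts, avgp, is_control)
            # frequent flyers: seen nearly everywhere, controls included; the
            # simulated SAINT probability is fooled on a fraction of records
            for prey in frequent:
                if rng.random() < cfg.detect_prob_frequent:
                    counts = _nb_counts(rng, freq_lambda[prey], cfg.dispersion, r)
                    fooled = rng.random() < cfg.frequent_highp_prob
                    avgp = 0.0 if is_control else _avgp(fooled)
                    _emit(bait, prey, line, counts, avgp, is_control)
            # named blocklist contaminants: abundant in every purification
            for prey in contaminants:
                counts = _nb_counts(rng, contam_lambda[prey], cfg.dispersion, r)
                avgp = 0.0 if is_control else _avgp(True)
                _emit(bait, prey, line, counts, avgp, is_control)

    df = pd.DataFrame(
        rows,
        columns=["bait", "prey", "cell_line", "avg_spec", "avg_p",
                 "replicate_specs", "is_control"],
    )
    table = InteractionTable(df=df, controls=dict(_CONTROL_IDS))
    truth = SimTruth(
        true_edges=true_edges,
        membrane_preys=membrane,
        frequent_preys=set(frequent),
        planted_avg_spec_threshold=planted_avg_spec_threshold(cfg),
    )
    return table, truth


def benchmark_recovery(
    filtered: pd.DataFrame,
    truth: SimTruth,
    *,
    calibrated_avg_spec: float | None = None,
    cluster_labels=None,
    planted_labels=None,
) -> dict[str, float]:
    """Precision / recall / F1 of a filtered interaction set against the plant.

    Optionally also reports the absolute error of a calibrated AvgSpec
    cutpoint against the planted threshold, and the adjusted Rand index of
    recovered vs planted cluster labels.
    """
    truth_baits = {b for edges in truth.true_edges.values() for b, _ in edges}
    got_baits = set(filtered["bait"].unique())
    if not got_baits <= truth_baits | {b for b in got_baits if b.startswith("CTRL")}:
        extra = got_baits - truth_baits
        raise ValidationError(f"filtered set contains baits unknown to the truth: {sorted(extra)[:5]}")
    predicted = {
        (line, b, p)
        for b, p, line in filtered[["bait", "prey", "cell_line"]].itertuples(index=False)
    }
    actual = {
        (line, b, p) for line, edges in truth.true_edges.items() for b, p in edges
    }
    tp = len(predicted & actual)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(actual) if actual else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    out = {"precision": precision, "recall": recall, "f1": f1,
           "n_predicted": float(len(predicted)), "n_true": float(len(actual))}
    if calibrated_avg_spec is not None:
        out["avg_spec_cutpoint_error"] = abs(
            calibrated_avg_spec - truth.planted_avg_spec_threshold
        )
    if cluster_labels is not None and planted_labels is not None:
        from sklearn.metrics import adjusted_rand_score

        out["cluster_ari"] = float(adjusted_rand_score(planted_labels, cluster_labels))
    return out


def simulate_wds_matrix(
    n_bait_families: int = 4,
    n_prey_modules: int = 5,
    baits_per_family: int = 4,
    preys_per_module: int = 30,
    within_mean: float = 20.0,
    noise_prob: float = 0.05,
    noise_mean: float = 1.5,
    seed: int = 0,
):
    """Bait x prey WDS matrix with planted bait families and prey modules.

    Each prey module loads on the baits of one family (modules beyond the
    family count load on two adjacent families, giving them a distinct
    support pattern); off-module entries are sparse low-level noise.

    Returns ``(matrix, prey_labels, bait_labels)`` where labels are the
    planted module / family assignments.
    """
    if n_prey_modules > 2 * n_bait_families:
        raise ValidationError("too many prey modules for the bait family count")
    rng = np.random.default_rng(seed)
    baits = [f"BAIT{i + 1:02d}" for i in range(n_bait_families * baits_per_family)]
    bait_family = np.repeat(np.arange(n_bait_families), baits_per_family)
    preys = [f"PREY{i + 1:03d}" for i in range(n_prey_modules * preys_per_module)]
    prey_module = np.repeat(np.arange(n_prey_modules), preys_per_module)

    def module_families(m: int) -> set[int]:
        if m < n_bait_families:
            return {m}
        return {m % n_bait_families, (m + 1) % n_bait_families}

    mat = np.zeros((len(baits), len(preys)))
    for j, m in enumerate(prey_module):
        fams = module_families(int(m))
        on = np.isin(bait_family, list(fams))
        mat[on, j] = rng.gamma(shape=4.0, scale=within_mean / 4.0, size=on.sum())
        off = ~on
        hits = rng.random(off.sum()) < noise_prob
        noise = rng.exponential(noise_mean, size=hits.sum())
        mat[np.flatnonzero(off)[hits], j] = noise
    matrix = pd.DataFrame(mat, index=baits, columns=preys)
    return (
        matrix,
        pd.Series(prey_module, index=preys, name="module"),
        pd.Series(bait_family, index=baits, name="family"),
    )


def simulate_marker_atlas(
    n_compartments: int = 20, markers_per_compartment: int = 15, seed: int = 0
):
    """Disjoint compartment marker sets, GMT-shaped."""
    from .io_formats import CompartmentAtlas

    compartments = {
        f"compartment_{c + 1:03d}": frozenset(
            f"MRK_{c + 1:03d}_{i + 1:02d}" for i in range(markers_per_compartment)
        )
        for c in range(n_compartments)
    }
    return CompartmentAtlas(compartments=compartments)


def simulate_localized_baits(
    atlas,
    n_baits: int = 200,
    preys_per_bait: int = 20,
    frac_home: float = 0.8,
    seed: int = 0,
):
    """Baits drawing ``frac_home`` of their preys from one home compartment.

    Returns ``(prey_sets, homes)``: a dict bait -> prey set and a dict
    bait -> home compartment name.
    """
    rng = np.random.default_rng(seed)
    names = list(atlas.compartments)
    prey_sets: dict[str, set[str]] = {}
    homes: dict[str, str] = {}
    pooled = sorted(set().union(*atlas.compartments.values()))
    for i in range(n_baits):
        bait = f"BAIT{i + 1:03d}"
        home = names[i % len(names)]
        homes[bait] = home
        home_markers = sorted(atlas.compartments[home])
        n_home = min(int(round(frac_home * preys_per_bait)), len(home_markers))
        chosen = set(rng.choice(home_markers, size=n_home, replace=False))
        others = [m for m in pooled if m not in atlas.compartments[home]]
        n_other = preys_per_bait - n_home
        chosen |= set(rng.choice(others, size=n_other, replace=False))
        prey_sets[bait] = chosen
    return prey_sets, homes


def simulate_replicate_matrix(
    n_preys: int = 300,
    n_replicates: int = 2,
    mu: float = 10.0,
    sigma_log: float = 1.8,
    shuffle_replicate: int | None = None,
    bait: str = "SIM",
    seed: int = 0,
):
    """Prey x replicate counts with a shared log-normal abundance profile.

    Replicates share per-prey Poisson intensities, giving the high rank
    correlation of well-behaved biological duplicates; setting
    ``shuffle_replicate`` permutes one column's prey assignment, emulating a
    failed acquisition that decorrelates from its siblings.
    """
    from .qc import ReplicateMatrix

    rng = np.random.default_rng(seed)
    lam = rng.lognormal(mean=np.log(mu), sigma=sigma_log, size=n_preys)
    counts = rng.poisson(lam[:, None], size=(n_preys, n_replicates))
    if shuffle_replicate is not None:
        counts[:, shuffle_replicate] = rng.permutation(counts[:, shuffle_replicate])
    frame = pd.DataFrame(
        counts,
        index=[f"PREY{i + 1:04d}" for i in range(n_preys)],
        columns=[f"rep{i + 1}" for i in range(n_replicates)],
    )
    return ReplicateMatrix(bait=bait, cell_line="HEK293", counts=frame)
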