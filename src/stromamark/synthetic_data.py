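"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study conditions the pipeline was designed for:
three replicate LC-MS runs of an 8-plex iTRAQ experiment comparing five
fibroblast samples (reference channel 113) against three cancer epithelial
cell lines, with 116 planted fibroblast-enriched and 44 planted
epithelial-enriched proteins among ~1000; a target-decoy score mixture with
a recoverable 1%-FDR cutoff per run; localization evidence drawn to a
0.53/0.16/0.31 secreted/membrane/intracellular mix with 95% exosome-catalog
membership; microarray vote tables with planted cancer-up/down genes; and
two-group plasma concentrations (42 cases at mean 61.6 ng/mL, 48 controls
at mean 45.0 ng/mL) plus right-censored survival records.

Every generator is a pure function of its :class:`SyntheticConfig` — a fixed
seed reproduces the tables bit-for-bit — and each returns, alongside the
tables, a truth object sufficient to score recovery without re-derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from stromamark.localization import (
    DEFAULT_MEMBRANE_TERMS,
    DEFAULT_SECRETED_TERMS,
    INTRACELLULAR,
    PLASMA_MEMBRANE,
    SECRETED,
)
from stromamark.quantitation import CALL_EPI, CALL_FIBRO, CALL_NEITHER, ChannelDesign

_INTRACELLULAR_TERMS = ("cytoplasm", "nucleus", "mitochondrion", "cytoskeleton")


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters shared by all generators."""

    seed: int = 0
    n_proteins: int = 1000
    n_runs: int = 3
    fraction_decoy: float = 0.5
    #: planted per-run score cutoffs at 1% FDR
    planted_thresholds: tuple[float, ...] = (2.0, 1.62, 2.01)
    target_fdr: float = 0.01
    planted_fibro_enriched: int = 116
    planted_epi_enriched: int = 44
    fc_effect: float = 8.0
    ratio_cv: float = 0.2
    localization_mix: tuple[float, float, float] = (0.53, 0.16, 0.31)
    exosome_rate: float = 0.95
    # vote model
    n_genes: int = 200
    planted_up_genes: int = 20
    planted_down_genes: int = 8
    vote_n_total: int = 25
    null_up_rate: float = 0.15
    # plasma model (concentrations in ng/mL)
    n_case: int = 42
    n_control: int = 48
    mean_case: float = 61.6
    mean_control: float = 45.0
    sd_case: float = 11.0
    sd_control: float = 8.0
    # survival model (times in months)
    n_subjects: int = 90
    hazard_ratio: float = 2.0
    median_survival_months: float = 51.0
    censor_horizon_months: float = 85.0

    def __post_init__(self):
        if not 0 <= self.fraction_decoy <= 1:
            raise ValueError("fraction_decoy must be in [0, 1]")
        if abs(sum(self.localization_mix) - 1.0) > 1e-9:
            raise ValueError("localization_mix must sum to 1")
        if min(self.localization_mix) < 0 or not 0 <= self.exosome_rate <= 1:
            raise ValueError("rates must be in [0, 1]")
        if self.fc_effect <= 0 or self.ratio_cv <= 0:
            raise ValueError("fc_effect and ratio_cv must be positive")
        if min(self.planted_fibro_enriched, self.planted_epi_enriched) < 0:
            raise ValueError("planted counts must be >= 0")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent substream per generator so stages can be re-run alone
    return np.random.default_rng([cfg.seed, stream])


def _accessions(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(n)]


# ---------------------------------------------------------------------------
# identifications
# ---------------------------------------------------------------------------

def generate_identifications(
    cfg: SyntheticConfig,
) -> tuple[list[pd.DataFrame], dict]:
    """Per-run identification tables with a recoverable planted FDR cutoff.

    Target scores follow a log-normal spread around each run's planted
    cutoff tau.  Decoys mimic a null: most sit well below tau, a tight clump
    of *duplicated* decoy scores just under tau forces the decoy/target
    ratio above ``target_fdr`` for every candidate cutoff below tau, and
    ``floor(target_fdr * n_targets_above)`` decoys are planted above tau as
    the tolerated contamination — so the estimated cutoff lands on the first
    observed score at or above tau.
    """
    rng = _rng(cfg, 1)
    n = cfg.n_proteins
    accs = _accessions(n)
    run_tables = []
    thresholds = list(cfg.planted_thresholds)[: cfg.n_runs]
    while len(thresholds) < cfg.n_runs:
        thresholds.append(2.0)

    for run_id, tau in enumerate(thresholds, start=1):
        scores = rng.lognormal(mean=np.log(tau) + 0.4, sigma=0.8, size=n)
        peptides = np.maximum(
            1, rng.poisson(3.0, size=n) + (scores > tau).astype(int)
        )
        rows = pd.DataFrame(
            {
                "accession": accs,
                "run_id": run_id,
                "unused_score": scores,
                "n_unique_peptides_conf": peptides,
                "coverage": np.round(rng.uniform(0.02, 0.8, size=n), 3),
                "is_decoy": 0,
            }
        )
        n_decoy = int(round(cfg.fraction_decoy * n))
        if n_decoy > 0:
            n_above = int(np.sum(scores > tau))
            n_hi = min(n_decoy, int(cfg.target_fdr * n_above))
            # paired clump just below tau: ties guarantee the ratio jumps
            # by >= 2 decoys at the first candidate under tau; the top pair
            # is pinned immediately below tau so the crossing is sharp
            n_clump = min(n_decoy - n_hi, max(10, n // 50))
            n_clump -= n_clump % 2
            n_low = n_decoy - n_hi - n_clump
            clump_pairs = np.r_[
                tau * (1 - 1e-6),
                rng.uniform(tau * 0.995, tau * 0.9995,
                            size=max(0, n_clump // 2 - 1)),
            ][: n_clump // 2]
            decoy_scores = np.concatenate(
                [
                    rng.uniform(tau * 1.02, scores.max(), size=n_hi),
                    np.repeat(clump_pairs, 2),
                    rng.uniform(0.05, tau * 0.9, size=n_low),
                ]
            )
            decoys = pd.DataFrame(
                {
                    "accession": [f"DECOY_{a}" for a in _accessions(n_decoy)],
                    "run_id": run_id,
                    "unused_score": decoy_scores,
                    "n_unique_peptides_conf": np.maximum(
                        1, rng.poisson(1.5, size=n_decoy)
                    ),
                    "coverage": np.round(rng.uniform(0.01, 0.2, size=n_decoy), 3),
                    "is_decoy": 1,
                }
            )
            rows = pd.concat([rows, decoys], ignore_index=True)
        rows["is_decoy"] = rows["is_decoy"].astype(bool)
        run_tables.append(rows)

    truth = {"thresholds": thresholds, "target_fdr": cfg.target_fdr}
    return run_tables, truth


# ---------------------------------------------------------------------------
# quantitation
# ---------------------------------------------------------------------------

def generate_quant(
    cfg: SyntheticConfig, design: ChannelDesign | None = None
) -> tuple[dict[int, pd.DataFrame], pd.DataFrame]:
    """Per-run iTRAQ ratio matrices with planted enrichment classes.

    Ratios are log-normal around the class-determined channel mean: 1 for
    every channel of a null protein; cancer channels at 1/``fc_effect``
    for fibroblast-enriched proteins; cancer channels at ``fc_effect`` for
    epithelial-enriched ones (ratios are relative to fibroblast channel
    113, which is identically 1).  Returns ``(matrices, truth)`` where
    ``truth`` has columns ``accession`` and ``true_call``.
    """
    design = design or ChannelDesign.default_8plex()
    rng = _rng(cfg, 2)
    n = cfg.n_proteins
    n_fib, n_epi = cfg.planted_fibro_enriched, cfg.planted_epi_enriched
    if n_fib + n_epi > n:
        raise ValueError("planted counts exceed n_proteins")
    accs = np.array(_accessions(n))
    true_call = np.array([CALL_NEITHER] * n, dtype=object)
    planted = rng.choice(n, size=n_fib + n_epi, replace=False)
    true_call[planted[:n_fib]] = CALL_FIBRO
    true_call[planted[n_fib:]] = CALL_EPI

    sigma = np.sqrt(np.log1p(cfg.ratio_cv**2))  # log-normal CV
    matrices = {}
    for run_id in range(1, cfg.n_runs + 1):
        data = {}
        for ch in design.channels:
            if ch == design.reference:
                data[ch] = np.ones(n)
                continue
            mu = np.ones(n)
            if design.group_of[ch] == "cancer":
                mu = np.where(true_call == CALL_FIBRO, 1.0 / cfg.fc_effect, mu)
                mu = np.where(true_call == CALL_EPI, cfg.fc_effect, mu)
            noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
            data[ch] = mu * noise
        matrices[run_id] = pd.DataFrame(data, index=accs)
        matrices[run_id].index.name = "accession"
    truth = pd.DataFrame({"accession": accs, "true_call": true_call})
    return matrices, truth


def quant_to_long(matrices: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Flatten per-run wide matrices into the long TSV dialect."""
    frames = []
    for run_id, qm in sorted(matrices.items()):
        m = qm.reset_index().melt(
            id_vars="accession", var_name="channel", value_name="ratio"
        )
        m.insert(1, "run_id", run_id)
        frames.append(m)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def generate_annotations(cfg: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotation records consistent with planted localization classes.

    Secreted-class proteins receive at least one secreted-tier evidence
    source (a component term, a signal peptide, or the non-classical
    predictor); membrane-class proteins a membrane-tier term and no
    secreted-tier evidence; intracellular proteins only intracellular
    terms.  ``exosome_hits`` is a positive count with probability
    ``exosome_rate`` regardless of class.
    """
    rng = _rng(cfg, 3)
    n = cfg.n_proteins
    accs = _accessions(n)
    classes = rng.choice(
        [SECRETED, PLASMA_MEMBRANE, INTRACELLULAR], size=n, p=cfg.localization_mix
    )
    sec_terms = sorted(DEFAULT_SECRETED_TERMS)
    mem_terms = sorted(DEFAULT_MEMBRANE_TERMS)
    rows = []
    for acc, klass in zip(accs, classes):
        terms: list[str] = []
        sp = ncs = False
        if klass == SECRETED:
            mode = rng.integers(3)
            if mode == 0:
                terms.append(str(rng.choice(sec_terms)))
            elif mode == 1:
                sp = True
            else:
                ncs = True
            if rng.random() < 0.2:  # contradictory membrane term; tier 1 wins
                terms.append(str(rng.choice(mem_terms)))
        elif klass == PLASMA_MEMBRANE:
            terms.append(str(rng.choice(mem_terms)))
            if rng.random() < 0.3:
                terms.append(str(rng.choice(_INTRACELLULAR_TERMS)))
        else:
            terms.append(str(rng.choice(_INTRACELLULAR_TERMS)))
        hits = int(rng.random() < cfg.exosome_rate) * (1 + int(rng.poisson(8)))
        rows.append(
            {
                "accession": acc,
                "cc_terms": ";".join(terms),
                "has_signal_peptide": sp,
                "nonclassical_secreted": ncs,
                "exosome_hits": hits,
            }
        )
    annotations = pd.DataFrame(rows)
    truth = pd.DataFrame({"accession": accs, "true_klass": classes})
    return annotations, truth


# ---------------------------------------------------------------------------
# votes
# ---------------------------------------------------------------------------

def generate_votes(
    cfg: SyntheticConfig, up_min: int = 15, down_max: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vote tables with planted cancer-up and cancer-down genes.

    Planted up genes draw ``n_up`` uniformly in [``up_min``, ``n_total``]
    and ``n_down`` in [0, ``down_max``]; planted down genes mirror this;
    null genes draw binomial votes at ``null_up_rate`` in each direction
    (clipped so totals stay consistent).
    """
    rng = _rng(cfg, 4)
    n = cfg.n_genes
    if cfg.planted_up_genes + cfg.planted_down_genes > n:
        raise ValueError("planted gene counts exceed n_genes")
    genes = [f"GENE{i:04d}" for i in range(n)]
    status = np.array(["null"] * n, dtype=object)
    planted = rng.choice(n, size=cfg.planted_up_genes + cfg.planted_down_genes,
                         replace=False)
    status[planted[: cfg.planted_up_genes]] = "up"
    status[planted[cfg.planted_up_genes:]] = "down"
    rows = []
    for gene, st in zip(genes, status):
        n_total = max(up_min + down_max,
                      cfg.vote_n_total + int(rng.integers(-3, 4)))
        if st == "up":
            n_up = int(rng.integers(up_min, n_total - down_max + 1))
            n_down = int(rng.integers(0, down_max + 1))
        elif st == "down":
            n_down = int(rng.integers(up_min, n_total - down_max + 1))
            n_up = int(rng.integers(0, down_max + 1))
        else:
            n_up = int(rng.binomial(n_total, cfg.null_up_rate))
            n_down = int(rng.binomial(n_total - n_up, cfg.null_up_rate))
        rows.append({"gene": gene, "n_up": n_up, "n_down": n_down,
                     "n_total": n_total})
    votes = pd.DataFrame(rows)
    truth = pd.DataFrame({"gene": genes, "true_status": status})
    return votes, truth


# ---------------------------------------------------------------------------
# plasma & survival
# ---------------------------------------------------------------------------

def normal_auc(mean_case: float, mean_control: float,
               sd_case: float, sd_control: float) -> float:
    """Closed-form AUC of a two-normal model: Phi(delta / sqrt(s1^2 + s2^2))."""
    from scipy.stats import norm

    delta = mean_case - mean_control
    return float(norm.cdf(delta / np.hypot(sd_case, sd_control)))


def generate_plasma(cfg: SyntheticConfig) -> pd.DataFrame:
    """Case/control plasma concentrations, normal truncated at zero.

    Columns: ``id``, ``concentration_ng_ml``, ``is_case``.
    """
    rng = _rng(cfg, 5)

    def _draw(n, mean, sd):
        out = rng.normal(mean, sd, size=n)
        while (out <= 0).any():  # truncate by redraw (negligible at 5+ sigma)
            bad = out <= 0
            out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        return out

    case = _draw(cfg.n_case, cfg.mean_case, cfg.sd_case)
    ctrl = _draw(cfg.n_control, cfg.mean_control, cfg.sd_control)
    return pd.DataFrame(
        {
            "id": [f"S{i:03d}" for i in range(cfg.n_case + cfg.n_control)],
            "concentration_ng_ml": np.concatenate([case, ctrl]),
            "is_case": [True] * cfg.n_case + [False] * cfg.n_control,
        }
    )


def generate_survival(cfg: SyntheticConfig) -> pd.DataFrame:
    """Two-group survival records with a planted hazard ratio.

    Event times are exponential; the high-marker group's hazard is
    ``hazard_ratio`` times the baseline (tuned so the pooled median sits
    near ``median_survival_months``).  Censoring is uniform administrative
    follow-up up to ``censor_horizon_months``.

    Columns: ``id``, ``time_months``, ``event``, ``group`` (marker_high /
    marker_low).
    """
    rng = _rng(cfg, 6)
    n = cfg.n_subjects
    n_high = n // 2
    base_hazard = np.log(2) / cfg.median_survival_months
    rows = []
    for i in range(n):
        high = i < n_high
        lam = base_hazard * (cfg.hazard_ratio if high else 1.0)
        t_event = rng.exponential(1.0 / lam)
        t_censor = rng.uniform(3.0, cfg.censor_horizon_months)
        t = min(t_event, t_censor)
        rows.append(
            {
                "id": f"T{i:03d}",
                "time_months": round(max(t, 0.1), 2),
                "event": t_event <= t_censor,
                "group": "marker_high" if high else "marker_low",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IHC
# ---------------------------------------------------------------------------

def generate_ihc(
    cfg: SyntheticConfig, n_samples: int = 80, cutoff: float = 0.043
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-image IOD/area measurements for stroma and epithelium regions.

    Half the sample-regions are planted positive (mean intensity above
    ``cutoff``), half negative; 1-3 images per sample-region.  Returns
    ``(measurements, truth)`` with truth column ``true_positive`` giving the
    planted mean-intensity class.
    """
    rng = _rng(cfg, 7)
    meas, truth = [], []
    for i in range(n_samples):
        sample = f"TMA{i:03d}"
        for region in ("stroma", "epithelium"):
            positive = bool(rng.random() < 0.5)
            # planted mean intensity clearly on one side of the cutoff
            mean_int = cutoff * (rng.uniform(1.5, 4.0) if positive
                                 else rng.uniform(0.1, 0.6))
            n_img = int(rng.integers(1, 4))
            intensities = mean_int * rng.uniform(0.9, 1.1, size=n_img)
            intensities += mean_int - intensities.mean()  # hold the mean exactly
            areas = rng.uniform(5e3, 5e4, size=n_img)
            for j in range(n_img):
                meas.append(
                    {
                        "sample": sample,
                        "region": region,
                        "image_id": f"{sample}_{region}_{j}",
                        "iod": intensities[j] * areas[j],
                        "area": areas[j],
                    }
                )
            truth.append(
                {"sample": sample, "region": region, "true_positive": positive}
            )
    return pd.DataFrame(meas), pd.DataFrame(truth)
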