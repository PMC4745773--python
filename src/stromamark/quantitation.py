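"""iTRAQ ratio quantitation and replicate-consistent enrichment calls.

Eight samples are labelled with 8-plex isobaric tags and quantified in one
LC-MS run as reporter-ion ratios to a reference channel.  In the design
emulated here, channels 113-117 carry five fibroblast samples (113 is the
reference, so its ratio is identically 1) and channels 118, 119 and 121
carry three cancer epithelial cell lines.

Per run and protein, the fold change is the ratio of the fibroblast-group
mean to the cancer-group mean of the channel ratios, and a two-sample t-test
(on log2 ratios by default — ratio noise is multiplicative) yields a p
value.  A protein is called *fibroblast-enriched* when FC >= ``fc_min`` and
p < ``alpha`` in every replicate run, *epithelial-enriched* when
FC <= 1/``fc_min`` and p < ``alpha`` in every run, and *neither* otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

FIBROBLAST = "fibroblast"
CANCER = "cancer"

CALL_FIBRO = "fibroblast_enriched"
CALL_EPI = "epithelial_enriched"
CALL_NEITHER = "neither"


@dataclass(frozen=True)
class ChannelDesign:
    """Mapping of iTRAQ channels to samples and groups.

    ``reference`` must be one of ``channels``; its ratio column is
    identically 1 and it belongs to a group like any other channel.
    """

    channels: tuple[str, ...]
    group_of: dict[str, str]
    reference: str
    sample_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.reference not in self.channels:
            raise ValueError(f"reference {self.reference!r} not among channels")
        groups = {self.group_of.get(c) for c in self.channels}
        if not {FIBROBLAST, CANCER} <= groups:
            raise ValueError("both fibroblast and cancer groups must be non-empty")

    def group_channels(self, group: str) -> list[str]:
        return [c for c in self.channels if self.group_of[c] == group]

    @classmethod
    def default_8plex(cls) -> "ChannelDesign":
        """Five fibroblast channels (113 reference) versus three cancer channels."""
        fibro = ["113", "114", "115", "116", "117"]
        cancer = ["118", "119", "121"]
        samples = ["CCD-18Co", "0426_NF", "0426_CAF", "1031_NF", "1031_CAF",
                   "SW620", "HT-29", "LoVo"]
        return cls(
            channels=tuple(fibro + cancer),
            group_of={c: FIBROBLAST for c in fibro} | {c: CANCER for c in cancer},
            reference="113",
            sample_of=dict(zip(fibro + cancer, samples)),
        )

    @classmethod
    def from_yaml(cls, path) -> "ChannelDesign":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        channels = tuple(str(c) for c in cfg["channels"])
        return cls(
            channels=channels,
            group_of={str(k): v for k, v in cfg["group_of"].items()},
            reference=str(cfg["reference"]),
            sample_of={str(k): v for k, v in cfg.get("sample_of", {}).items()},
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "channels": list(self.channels),
                    "group_of": dict(self.group_of),
                    "reference": self.reference,
                    "sample_of": dict(self.sample_of),
                },
                fh,
            )


def two_sample_ttest(
    a, b, two_tailed: bool = True, equal_var: bool = True
) -> tuple[float, float]:
    """Classical two-sample t-test.

    ``equal_var=True`` gives the pooled-variance Student test, ``False`` the
    Welch variant.  Degenerate zero-variance inputs are resolved by limits:
    identical constant groups give (0, 1); constant groups at different
    levels give (±inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if not two_tailed:
        p = p / 2 if t > 0 else 1 - p / 2
    return float(t), float(p)


def per_run_enrichment(
    qm: pd.DataFrame,
    design: ChannelDesign,
    log_scale: bool = True,
    equal_var: bool = True,
    median_normalize: bool = False,
) -> pd.DataFrame:
    """Fold change and p value per protein for one run's ratio matrix.

    Parameters
    ----------
    qm
        Wide matrix, index = accession, columns = channel tags, values =
        ratios to the reference channel (positive; NaN = missing).
    design
        Channel-to-group assignment; the reference channel participates in
        its group's sample vector (its ratio is the constant 1).
    log_scale
        Run the t-test on log2 ratios (default).  The fold change itself is
        always the ratio of raw group means.
    median_normalize
        Optionally divide each channel column by its median first
        (an approximation of instrument-software bias correction).

    Returns a frame indexed like ``qm`` with columns ``fc``, ``p`` and
    ``quantifiable`` (False when either group has fewer than two non-missing
    ratios; such rows carry NaN fc/p).
    """
    missing_cols = [c for c in design.channels if c not in qm.columns]
    if missing_cols:
        raise ValueError(f"ratio matrix lacks channels: {missing_cols}")
    values = qm[list(design.channels)].to_numpy(dtype=float)
    if np.nanmin(values) <= 0 if values.size else False:
        raise ValueError("iTRAQ ratios must be positive")
    if median_normalize:
        med = np.nanmedian(values, axis=0, keepdims=True)
        values = values / med
        ref_idx = design.channels.index(design.reference)
        values[:, ref_idx] = qm[design.reference].to_numpy(dtype=float)

    idx = [design.channels.index(c) for c in design.group_channels(FIBROBLAST)]
    jdx = [design.channels.index(c) for c in design.group_channels(CANCER)]
    fib = values[:, idx]
    can = values[:, jdx]

    n_fib = np.sum(~np.isnan(fib), axis=1)
    n_can = np.sum(~np.isnan(can), axis=1)
    quantifiable = (n_fib >= 2) & (n_can >= 2)

    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.nanmean(fib, axis=1) / np.nanmean(can, axis=1)
        ta, tb = (np.log2(fib), np.log2(can)) if log_scale else (fib, can)
        res = stats.ttest_ind(
            ta, tb, axis=1, equal_var=equal_var, nan_policy="omit"
        )
        p = np.asarray(res.pvalue, dtype=float)
    # zero-variance rows: identical groups -> p=1, separated -> p=0
    zero_var = quantifiable & ~np.isfinite(p)
    if zero_var.any():
        same = np.isclose(np.nanmean(ta, axis=1), np.nanmean(tb, axis=1))
        p = np.where(zero_var & same, 1.0, p)
        p = np.where(zero_var & ~same, 0.0, p)
    fc = np.where(quantifiable, fc, np.nan)
    p = np.where(quantifiable, p, np.nan)
    return pd.DataFrame(
        {"fc": fc, "p": p, "quantifiable": quantifiable}, index=qm.index
    )


def call_enrichment(
    per_run: pd.DataFrame,
    fc_min: float = 2.0,
    alpha: float = 0.05,
    require_all: bool = True,
    n_runs: int | None = None,
) -> pd.DataFrame:
    """Replicate-consistent enrichment calls from per-run (fc, p) results.

    ``per_run`` is a long frame with columns ``accession``, ``run_id``,
    ``fc``, ``p`` (one row per protein and run; rows with NaN fc/p count as
    unquantifiable in that run).  With ``require_all`` (default) a protein
    must be quantifiable and pass in *every* run — the number of runs is
    taken from the table unless ``n_runs`` is given.

    Returns one row per accession with ``average_fc`` (arithmetic mean of
    the per-run fold changes where defined, always on the
    fibroblast/cancer scale) and ``call``.
    """
    required = {"accession", "run_id", "fc", "p"}
    if not required <= set(per_run.columns):
        raise ValueError(f"per-run results need columns {sorted(required)}")
    if n_runs is None:
        n_runs = per_run["run_id"].nunique()
    if per_run.duplicated(["accession", "run_id"]).any():
        raise ValueError("duplicate (accession, run_id) rows in per-run results")
    if per_run["run_id"].nunique() > n_runs:
        raise ValueError("per-run table has more runs than n_runs")

    fc_w = per_run.pivot(index="accession", columns="run_id", values="fc")
    p_w = per_run.pivot(index="accession", columns="run_id", values="p")
    fc = fc_w.to_numpy(dtype=float)
    p = p_w.to_numpy(dtype=float)
    ok = ~(np.isnan(fc) | np.isnan(p))
    sig = ok & (p < alpha)
    fib_pass = sig & (fc >= fc_min)
    epi_pass = sig & (fc <= 1.0 / fc_min)
    if require_all:
        is_fib = (np.sum(fib_pass, axis=1) == n_runs) & (fc_w.shape[1] == n_runs)
        is_epi = (np.sum(epi_pass, axis=1) == n_runs) & (fc_w.shape[1] == n_runs)
    else:
        is_fib = np.sum(fib_pass, axis=1) >= 1
        is_epi = np.sum(epi_pass, axis=1) >= 1
    call = np.select([is_fib, is_epi], [CALL_FIBRO, CALL_EPI], default=CALL_NEITHER)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> NaN mean
        avg = np.nanmean(np.where(ok, fc, np.nan), axis=1)
    return pd.DataFrame(
        {"accession": fc_w.index, "average_fc": avg, "call": call}
    ).reset_index(drop=True)


def call_counts(calls: pd.DataFrame) -> dict[str, int]:
    counts = calls["call"].value_counts()
    return {k: int(counts.get(k, 0)) for k in (CALL_FIBRO, CALL_EPI, CALL_NEITHER)}


def read_quant_long(path) -> dict[int, pd.DataFrame]:
    """Read a long-format ratio TSV (accession, run_id, channel, ratio).

    Returns per-run wide matrices (accession x channel).
    """
    df = pd.read_csv(path, sep="\t", dtype={"channel": str})
    out = {}
    for run_id, g in df.groupby("run_id", sort=True):
        out[int(run_id)] = g.pivot(index="accession", columns="channel", values="ratio")
    return out


def enrichment_pipeline(
    matrices: dict[int, pd.DataFrame],
    design: ChannelDesign,
    fc_min: float = 2.0,
    alpha: float = 0.05,
    require_all: bool = True,
    log_scale: bool = True,
    equal_var: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run per-run enrichment on every run and make the final calls.

    Returns ``(per_run_long, calls)``.
    """
    rows = []
    for run_id, qm in sorted(matrices.items()):
        res = per_run_enrichment(qm, design, log_scale=log_scale, equal_var=equal_var)
        res = res.reset_index().rename(columns={res.index.name or "index": "accession"})
        res["run_id"] = run_id
        rows.append(res[["accession", "run_id", "fc", "p", "quantifiable"]])
    per_run_long = pd.concat(rows, ignore_index=True)
    calls = call_enrichment(
        per_run_long, fc_min=fc_min, alpha=alpha,
        require_all=require_all, n_runs=len(matrices),
    )
    return per_run_long, calls
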