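"""Non-stationary null statistic-field simulator and frequentist validation.

Surrogate null subjects are built from independent unit-variance Gaussian
scans given piecewise-constant smoothness: a random Voronoi layout assigns
each cell its own FWHM (uniform on a range), the composite is re-smoothed
globally to preclude sharp transitions, and a mean-effect GLM yields the
subject's t-field.  Regional resel counts come from the GLM residuals, so
the inference modules can be audited for frequentist operating
characteristics (family-wise error of flagged regions, rate of decisive
Bayes factors) under a truthful null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import VolumeGrid, estimate_rpv
from .peaks import PeakConfig, find_peaks
from .multinomial import EventCounts, NullPattern, chisq_pattern_test
from .ffx import CredibleSpec, run_ffx, pool_counts
from .rfx import SubjectCounts, MCMCConfig, rfx_sample, rfx_intervals

logger = logging.getLogger(__name__)

_FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass(frozen=True)
class NullSimConfig:
    """Null-simulation settings.

    The defaults follow the reference simulation design: 64^3 lattice
    (1 unit = 1 mm), 84 scans per subject, 20 Voronoi smoothness cells
    with FWHM ~ U[4, 10], global re-smoothing at FWHM 2, a 1000-subject
    corpus, and 150 experiments of 20 subjects.  ``scaled_down`` gives a
    cheaper profile with the same statistical structure for routine runs.
    """

    shape: tuple = (64, 64, 64)
    n_scans: int = 84
    n_voronoi_regions: int = 20
    fwhm_range: tuple = (4.0, 10.0)
    global_fwhm: float = 2.0
    n_subjects_corpus: int = 1000
    group_size: int = 20
    n_experiments: int = 150
    n_partition_regions: tuple = (5, 10, 15, 20)
    n_anatomical_regions: int = 116
    threshold: float = 3.0
    x: float = 0.99
    seed: int = 0
    rfx_chains: int = 2
    rfx_iters: int = 8000
    rfx_burn_in: int = 3000

    def __post_init__(self):
        if self.fwhm_range[0] < 1:
            raise ValueError("fwhm_range low bound must be >= 1")
        if self.group_size > self.n_subjects_corpus:
            raise ValueError("group_size cannot exceed the corpus size")
        for name in ("n_scans", "n_voronoi_regions", "n_subjects_corpus",
                     "group_size", "n_experiments", "n_anatomical_regions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def scaled_down(cls, **overrides):
        """Reduced profile: 32^3 lattice, 24 scans, 300 subjects, 100
        experiments of 10; otherwise identical conditions."""
        base = dict(shape=(32, 32, 32), n_scans=24, n_subjects_corpus=300,
                    group_size=10, n_experiments=100,
                    n_anatomical_regions=60)
        base.update(overrides)
        return cls(**base)

    @property
    def grid(self) -> VolumeGrid:
        return VolumeGrid.full(self.shape)


@dataclass(frozen=True)
class HomogeneousPoissonModel:
    """Homogeneous Poisson event process with rate per resel."""

    rate: float

    def __post_init__(self):
        if not self.rate > 0:
            raise ValueError("rate must be > 0")


@dataclass(frozen=True)
class FWERReport:
    """Frequentist operating characteristics of null-group experiments."""

    mode: str                    # "ffx" or "rfx"
    per_partition: dict          # N -> summary dict
    n_experiments: int
    group_size: int
    seed: int

    @property
    def max_fwer(self) -> float:
        return max(v["fwer"] for v in self.per_partition.values())

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "L": self.n_experiments,
            "group_size": self.group_size,
            "seed": self.seed,
            "per_partition": {str(k): v for k, v in self.per_partition.items()},
            "max_fwer": self.max_fwer,
        }


def voronoi_parcellation(shape, n_regions: int, seed) -> np.ndarray:
    """Label a lattice by nearest of ``n_regions`` random seed voxels.

    Euclidean distance, ties resolved to the lowest seed index; labels run
    1..n_regions and every label is non-empty (degenerate draws are
    redrawn).
    """
    shape = tuple(int(s) for s in shape)
    n_vox = int(np.prod(shape))
    if n_regions > n_vox:
        raise ValueError("more regions than voxels")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    coords = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                  indexing="ij"), axis=-1).reshape(-1, 3)
    for _ in range(100):
        idx = rng.choice(n_vox, size=n_regions, replace=False)
        seeds = coords[idx].astype(float)
        # chunked distance computation; argmin takes the lowest index on ties
        labels = np.empty(n_vox, dtype=np.int32)
        chunk = 1 << 16
        for start in range(0, n_vox, chunk):
            block = coords[start:start + chunk].astype(float)
            d2 = ((block[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
            labels[start:start + chunk] = np.argmin(d2, axis=1) + 1
        if np.unique(labels).size == n_regions:
            return labels.reshape(shape)
    raise RuntimeError("could not draw a non-degenerate parcellation")


def _smooth(vol, fwhm):
    if fwhm <= 0:
        return vol
    return ndimage.gaussian_filter(vol, sigma=fwhm * _FWHM_TO_SIGMA,
                                   mode="reflect", truncate=4.0)


def _simulate_scans(cfg: NullSimConfig, rng: np.random.Generator):
    """Scans for one subject under its own fixed non-stationary layout."""
    layout = voronoi_parcellation(cfg.shape, cfg.n_voronoi_regions, rng)
    fwhms = rng.uniform(*cfg.fwhm_range, size=cfg.n_voronoi_regions)
    region_masks = [layout == j + 1 for j in range(cfg.n_voronoi_regions)]
    scans = np.empty((cfg.n_scans,) + cfg.shape, dtype=np.float32)
    for s in range(cfg.n_scans):
        noise = rng.standard_normal(cfg.shape).astype(np.float32)
        composite = np.zeros(cfg.shape, dtype=np.float32)
        for mask_r, f in zip(region_masks, fwhms):
            composite[mask_r] = _smooth(noise, f)[mask_r]
        scans[s] = _smooth(composite, cfg.global_fwhm)
    return scans


def _t_field(scans):
    n = scans.shape[0]
    mean = scans.mean(axis=0)
    sd = scans.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, np.inf)
    return mean / (sd / np.sqrt(n))


def simulate_null_subject(cfg: NullSimConfig, seed) -> np.ndarray:
    """Simulate one null subject and return its mean-effect t-field
    (df = n_scans - 1)."""
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    return _t_field(_simulate_scans(cfg, rng))


def _subject_summary(cfg: NullSimConfig, rng, anat_labels, n_regions):
    """Per-region event counts and resels for one simulated null subject."""
    scans = _simulate_scans(cfg, rng)
    t = _t_field(scans)
    mean = scans.mean(axis=0)
    residuals = scans - mean
    grid = cfg.grid
    rpv = estimate_rpv(residuals, grid, df=cfg.n_scans - 1)
    resels = np.bincount(anat_labels.ravel(), weights=rpv.rpv.ravel(),
                         minlength=n_regions + 1)[1:]
    events = find_peaks(t, grid, PeakConfig(threshold=cfg.threshold))
    if len(events):
        peak_labels = anat_labels[tuple(events.coords.T)]
        counts = np.bincount(peak_labels, minlength=n_regions + 1)[1:]
    else:
        counts = np.zeros(n_regions, dtype=np.int64)
    return counts, resels


def build_null_corpus(cfg: NullSimConfig):
    """Simulate the null corpus and reduce it to regional summaries.

    One "anatomical-style" Voronoi parcellation (distinct from the
    per-subject smoothness layouts) is fixed for the whole corpus, playing
    the role of a labelled atlas; each subject contributes its per-region
    event counts at the configured threshold and per-region resel counts
    from its own GLM residuals.

    Returns a dict with ``labels`` (the parcellation), ``counts`` and
    ``resels`` (both (n_subjects, n_regions)).
    """
    ss = np.random.SeedSequence(cfg.seed)
    anat_seed, *subject_seeds = ss.spawn(cfg.n_subjects_corpus + 1)
    labels = voronoi_parcellation(cfg.shape, cfg.n_anatomical_regions,
                                  np.random.default_rng(anat_seed))
    R = cfg.n_anatomical_regions
    counts = np.empty((cfg.n_subjects_corpus, R), dtype=np.int64)
    resels = np.empty((cfg.n_subjects_corpus, R))
    for i, sseed in enumerate(subject_seeds):
        rng = np.random.default_rng(sseed)
        counts[i], resels[i] = _subject_summary(cfg, rng, labels, R)
        if (i + 1) % 50 == 0:
            logger.info("simulated %d/%d null subjects", i + 1,
                        cfg.n_subjects_corpus)
    return {"labels": labels, "counts": counts, "resels": resels,
            "config": cfg}


def simulate_poisson_counts(model: HomogeneousPoissonModel, resels,
                            seed) -> EventCounts:
    """Draw independent regional Poisson counts with rates rate*|A_j|.

    The unconditional form of the null event process; conditioning the
    draws on their total recovers the multinomial pattern likelihood.
    """
    resels = np.asarray(
        getattr(resels, "resels", resels), dtype=float)
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    d = rng.poisson(model.rate * resels)
    return EventCounts(d=d)


def _partition_group(counts, resels, selected, include_rest):
    """Reduce base-region summaries to the experiment's partition.

    ``selected`` indexes atlas regions kept individually; the complement is
    merged into one rest-of-volume region when ``include_rest``.
    """
    sel_counts = counts[:, selected]
    sel_resels = resels[:, selected]
    if include_rest:
        rest_mask = np.ones(counts.shape[1], dtype=bool)
        rest_mask[selected] = False
        rest_counts = counts[:, rest_mask].sum(axis=1, keepdims=True)
        rest_resels = resels[:, rest_mask].sum(axis=1, keepdims=True)
        return (np.concatenate([sel_counts, rest_counts], axis=1),
                np.concatenate([sel_resels, rest_resels], axis=1))
    return sel_counts, sel_resels


def run_fwer_experiment(cfg: NullSimConfig, mode: str = "ffx",
                        corpus: dict = None) -> FWERReport:
    """Estimate null operating characteristics over simulated experiments.

    For each of L experiments a random group of subjects and a random
    subset of N atlas regions (plus the rest-of-volume complement; the
    full-atlas case N = n_anatomical_regions omits it) are drawn, counts
    and resels are pooled, and the inference is run at the configured
    credible level.  The family-wise error is the fraction of experiments
    with at least one region whose penalised interval excludes its a_j;
    fixed-effects runs also tabulate Bayes factors against the decisive
    threshold of 20.
    """
    if mode not in ("ffx", "rfx"):
        raise ValueError("mode must be 'ffx' or 'rfx'")
    if corpus is None:
        corpus = build_null_corpus(cfg)
    counts, resels = corpus["counts"], corpus["resels"]
    S, R = counts.shape
    exp_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    mcmc_seeds = np.random.default_rng(
        np.random.SeedSequence((cfg.seed, 2))).integers(
            0, 2**31 - 1, size=(len(cfg.n_partition_regions),
                                cfg.n_experiments))

    per_partition = {}
    for ni, N in enumerate(cfg.n_partition_regions):
        include_rest = N < R
        n_regions = N + 1 if include_rest else N
        flagged = 0
        n_bf20 = 0
        max_log_bf = -np.inf
        for l in range(cfg.n_experiments):
            group = exp_rng.choice(S, size=cfg.group_size, replace=False)
            for _ in range(100):
                selected = np.sort(exp_rng.choice(R, size=N, replace=False))
                d_g, r_g = _partition_group(counts[group], resels[group],
                                            selected, include_rest)
                if r_g.sum(axis=0).min() > 1e-6:
                    break
                logger.warning("redrawing regions with ~zero resels")
            if mode == "ffx":
                pooled_d, null = pool_counts(list(d_g), list(r_g))
                res = run_ffx(pooled_d, null, x=cfg.x)
                any_flag = any(f != "null" for f in res.flags)
                max_log_bf = max(max_log_bf, res.log_bayes_factor_10)
                n_bf20 += int(res.decisive)
            else:
                subj_nulls = [NullPattern(r / r.sum()) for r in r_g]
                data = SubjectCounts(
                    counts=tuple(EventCounts(dv) for dv in d_g),
                    nulls=tuple(subj_nulls), resels=r_g)
                mcfg = MCMCConfig(chains=cfg.rfx_chains, iters=cfg.rfx_iters,
                                  burn_in=cfg.rfx_burn_in,
                                  seed=int(mcmc_seeds[ni, l]))
                post = rfx_sample(data, cfg=mcfg)
                spec = CredibleSpec(x=cfg.x, n=n_regions)
                _, flags = rfx_intervals(post, data.reference_null(), spec)
                any_flag = any(f != "null" for f in flags)
            flagged += int(any_flag)
        summary = {
            "fwer": flagged / cfg.n_experiments,
            "n_flagged": flagged,
            "n_regions": n_regions,
            "include_rest": include_rest,
        }
        if mode == "ffx":
            summary["n_bf_ge_20"] = n_bf20
            summary["bf_rate"] = n_bf20 / cfg.n_experiments
            summary["max_log_bf"] = float(max_log_bf)
        per_partition[N] = summary
        logger.info("N=%d (%s): FWER=%.3f", N, mode, summary["fwer"])
    return FWERReport(mode=mode, per_partition=per_partition,
                      n_experiments=cfg.n_experiments,
                      group_size=cfg.group_size, seed=cfg.seed)


def null_spm_sanity(spms, grid: VolumeGrid, partition, t: float = 3.0):
    """Check that pooled event fractions match the relative resel counts.

    Counts peaks above ``t`` over the given statistic maps, pools them over
    the partition, and reports the Pearson chi-square test plus the
    fixed-effects Bayes factor; the null is called rejected when the Bayes
    factor reaches 20.  With no events the report carries k = 0 and no
    test.
    """
    spms = np.asarray(spms)
    if spms.ndim == 3:
        spms = spms[None]
    if spms.shape[0] < 1:
        raise ValueError("need at least one statistic map")
    n = partition.n_regions
    pooled = np.zeros(n, dtype=np.int64)
    for vol in spms:
        events = find_peaks(vol, grid, PeakConfig(threshold=t))
        if len(events):
            labels = partition.labels[tuple(events.coords.T)]
            pooled += np.bincount(labels[labels > 0], minlength=n + 1)[1:]
    k = int(pooled.sum())
    report = {"k": k, "d": pooled.tolist(),
              "rel_volume": partition.rel_volume.tolist()}
    if k == 0:
        report["status"] = "no test (k = 0)"
        return report
    null = NullPattern(partition.rel_volume)
    stat, df, p = chisq_pattern_test(EventCounts(pooled), null)
    res = run_ffx(EventCounts(pooled), null)
    report.update({
        "status": "tested",
        "chisq": stat, "chisq_df": df, "chisq_p": p,
        "log_bayes_factor_10": res.log_bayes_factor_10,
        "null_rejected_bf20": bool(res.decisive),
    })
    return report
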