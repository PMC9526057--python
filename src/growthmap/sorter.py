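"""Processing of large-particle sorter records into residual phenotypes.

A sorter reports, per object, a time-of-flight (TOF, a proxy for animal
length) and an optical extinction (EXT); EXT normalized by TOF (norm.EXT) is
a proxy for animal width. Raw object tables mix animals with debris
(bacterial clumps, shed cuticles, next-generation larvae), so the pipeline
is: gate animals with a Gaussian mixture on (log TOF, log EXT), convert to
microns, summarize wells by medians, drop wells with implausible animal
counts, and remove assay-day batch effects with a linear model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def norm_ext(tof, ext):
    """Width proxy: optical extinction normalized by time-of-flight."""
    tof = np.asarray(tof, dtype=float)
    ext = np.asarray(ext, dtype=float)
    if np.any(tof <= 0):
        raise ValueError("TOF must be positive")
    return ext / tof


@dataclass(frozen=True)
class Calibration:
    """Affine micron conversion, one (slope, intercept) per measure.

    Instrument-specific coefficients; identity by default. Downstream
    correlation-based mapping is invariant to this transform.
    """

    length_slope: float = 1.0
    length_intercept: float = 0.0
    width_slope: float = 1.0
    width_intercept: float = 0.0


def to_microns(values, slope: float = 1.0, intercept: float = 0.0) -> np.ndarray:
    """Affine conversion of an instrument measure to microns."""
    out = slope * np.asarray(values, dtype=float) + intercept
    if np.any(out < 0):
        log.warning("micron conversion produced negative values")
    return out


def gate_animals(
    objects: pd.DataFrame,
    max_components: int = 3,
    mahalanobis_cutoff: float = 3.0,
    seed: int = 0,
    min_objects: int = 20,
) -> pd.DataFrame:
    """Label each sorter object as animal (keep=True) or non-animal.

    Fits Gaussian mixtures with 1..max_components full-covariance components
    on (log TOF, log EXT), selects the component count by BIC, and calls the
    component with the largest mean log TOF the animal cluster; any other
    component whose mean lies within ``mahalanobis_cutoff`` of the animal
    component (under its covariance) is merged into it. Deterministic given
    ``seed``. Returns a copy with added ``component`` and ``keep`` columns.
    """
    if len(objects) < min_objects:
        raise ValueError(f"need >= {min_objects} objects to gate, got {len(objects)}")
    out = objects.copy()
    X = np.column_stack([np.log(out["TOF"].to_numpy()), np.log(out["EXT"].to_numpy())])
    if not np.isfinite(X).all():
        raise ValueError("TOF and EXT must be positive and finite")
    if np.allclose(X, X[0]):
        warnings.warn("all objects identical; labeling everything animal")
        out["component"] = 0
        out["keep"] = True
        return out
    best, best_bic = None, np.inf
    for k in range(1, max_components + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=2, random_state=seed
        ).fit(X)
        bic = gm.bic(X)
        if bic < best_bic - 1e-9:
            best, best_bic = gm, bic
    labels = best.predict(X)
    animal = int(np.argmax(best.means_[:, 0]))
    keep_components = {animal}
    prec = np.linalg.inv(best.covariances_[animal])
    for k in range(best.n_components):
        delta = best.means_[k] - best.means_[animal]
        if float(delta @ prec @ delta) <= mahalanobis_cutoff**2:
            keep_components.add(k)
    out["component"] = labels
    out["keep"] = np.isin(labels, sorted(keep_components))
    return out


def summarize_wells(
    gated: pd.DataFrame, calibration: Calibration | None = None
) -> pd.DataFrame:
    """Per-well medians over animal objects only.

    Expects the gated object table (columns strain, well, hour, TOF, EXT,
    keep). Lengths come from TOF, widths from norm.EXT, both through the
    micron calibration. Wells where every object was gated out get
    ``n_animals=0`` and NaN medians.
    """
    cal = calibration or Calibration()
    g = gated.copy()
    g["length_um"] = to_microns(g["TOF"], cal.length_slope, cal.length_intercept)
    g["width_um"] = to_microns(
        norm_ext(g["TOF"], g["EXT"]), cal.width_slope, cal.width_intercept
    )
    rows = []
    for (strain, well, hour), grp in g.groupby(["strain", "well", "hour"], sort=True):
        animals = grp[grp["keep"]]
        rows.append(
            (
                strain,
                well,
                hour,
                len(animals),
                animals["length_um"].median() if len(animals) else np.nan,
                animals["width_um"].median() if len(animals) else np.nan,
            )
        )
    return pd.DataFrame(
        rows, columns=["strain", "well", "hour", "n_animals", "length_um", "width_um"]
    )


def filter_wells(summaries: pd.DataFrame, min_n: int = 3, max_n: int = 100) -> pd.DataFrame:
    """Drop wells with fewer than ``min_n`` or more than ``max_n`` animals.

    Boundaries are inclusive: wells with exactly 3 or exactly 100 animals are
    retained under the defaults.
    """
    keep = (summaries["n_animals"] >= min_n) & (summaries["n_animals"] <= max_n)
    return summaries[keep].reset_index(drop=True)


def residualize(values: pd.Series, batch) -> pd.Series:
    """Residuals of a least-squares fit of value on batch indicators.

    With an intercept plus batch dummies the fitted value for each
    observation is its batch mean, so residuals are batch-centered values;
    residuals sum to zero within every batch. A batch with a single
    observation yields a residual of exactly 0 for it (logged).
    """
    values = pd.Series(values).astype(float)
    batch = pd.Series(batch, index=values.index)
    sizes = batch.value_counts()
    if (sizes == 1).any():
        log.warning("%d batch(es) have a single observation; their residuals are 0",
                    int((sizes == 1).sum()))
    resid = values - values.groupby(batch).transform("mean")
    resid.name = values.name
    return resid


def compare_timepoints(
    wells: pd.DataFrame,
    strain_a: str,
    strain_b: str,
    measure: str = "length_um",
    adjust: str = "fdr_bh",
    min_wells: int = 2,
) -> pd.DataFrame:
    """Per-hour two-sample Welch test between two strains on well medians.

    Returns one row per hour present in both strains with ``min_wells`` wells
    each: raw and multiplicity-adjusted p-values (across hours) and the
    effect direction. Hours missing in either strain are skipped and logged.
    """
    rows = []
    for hour in sorted(wells["hour"].unique()):
        a = wells.loc[(wells["strain"] == strain_a) & (wells["hour"] == hour), measure].dropna()
        b = wells.loc[(wells["strain"] == strain_b) & (wells["hour"] == hour), measure].dropna()
        if len(a) < min_wells or len(b) < min_wells:
            log.info("hour %s skipped: not enough wells in both strains", hour)
            continue
        diff = a.mean() - b.mean()
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        direction = "none" if diff == 0 else (f"{strain_a}>{strain_b}" if diff > 0 else f"{strain_b}>{strain_a}")
        rows.append((hour, len(a), len(b), diff, p, direction))
    out = pd.DataFrame(
        rows, columns=["hour", "n_a", "n_b", "mean_diff", "p_raw", "direction"]
    )
    if len(out):
        out["p_adj"] = multipletests(out["p_raw"], method=adjust)[1]
        out.loc[out["p_adj"] >= 1.0, "p_adj"] = 1.0
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out


def process_sorter_table(
    raw: pd.DataFrame,
    calibration: Calibration | None = None,
    max_components: int = 3,
    min_n: int = 3,
    max_n: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Full object-to-well pipeline: gate, convert, summarize, filter."""
    gated = gate_animals(raw, max_components=max_components, seed=seed)
    return filter_wells(summarize_wells(gated, calibration), min_n=min_n, max_n=max_n)
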