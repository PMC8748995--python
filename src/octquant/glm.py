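"""ROI extraction and the scattering generalized linear model.

The scattering coefficient of brain tissue is modelled as a linear function
of its two dominant structural sources,

    mu_s = b + k1 * GallyasOD + k2 * COPA

where ``k1`` captures the myelin contribution, ``k2`` the neuronal cell-body
contribution and the intercept ``b`` the residual scattering sources
(extracellular matrix and the like).  COPA is forced to zero on white-matter
rows before regression — white matter contains essentially only glia, which
do not contribute to scattering at these scales — and a single (b, k1) pair
is shared between grey and white matter.  The univariate variant drops the
COPA column.

Coefficients solve the ordinary least-squares problem
beta = (X^T X)^-1 X^T y (computed via an orthogonal decomposition for
conditioning); goodness of fit is summarised by the squared Pearson
correlation R^2 and the range-normalised RMSE, and predictor relevance by
partial correlation coefficients and two-sided t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ROI_TABLE_COLUMNS = ["roi_id", "mean_mu_s", "mean_od", "mean_copa",
                     "tissue_class", "layer", "region"]


@dataclass
class ROI:
    """A circular region of interest in map coordinates (um)."""

    roi_id: str
    center_x: float
    center_y: float
    radius: float
    layer: str = ""
    tissue_class: str = "grey"
    region: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")
        if self.tissue_class not in {"grey", "white"}:
            raise ValueError(f"unknown tissue_class {self.tissue_class!r}")


class CollinearityError(ValueError):
    """The design matrix is rank deficient."""


class UndefinedStatisticError(ValueError):
    """A correlation or R^2 is undefined (zero variance input)."""


@dataclass
class GLMFit:
    beta: np.ndarray                  # (b, k1[, k2])
    se: np.ndarray
    cov_beta: np.ndarray
    p_values: np.ndarray              # two-sided t-test per coefficient
    p_values_corrected: np.ndarray    # Bonferroni across coefficients
    r2: float
    nrmse: float
    n: int
    model: str                        # {"univariate", "multivariate"}
    term_names: Sequence[str] = field(default_factory=list)
    pcc: dict = field(default_factory=dict)   # predictor name -> PCC

    @property
    def intercept(self) -> float:
        return float(self.beta[0])

    @property
    def k1(self) -> float:
        return float(self.beta[1])

    @property
    def k2(self) -> Optional[float]:
        return float(self.beta[2]) if len(self.beta) > 2 else None

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Per-coefficient (lower, upper) confidence bounds."""
        dof = self.n - len(self.beta)
        t = stats.t.ppf(1 - alpha / 2, dof)
        return np.column_stack((self.beta - t * self.se, self.beta + t * self.se))

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "n": self.n,
            "terms": list(self.term_names),
            "beta": [float(v) for v in self.beta],
            "se": [float(v) for v in self.se],
            "p_values": [float(v) for v in self.p_values],
            "p_values_corrected": [float(v) for v in self.p_values_corrected],
            "r2": float(self.r2),
            "nrmse": float(self.nrmse),
            "pcc": {k: float(v) for k, v in self.pcc.items()},
        }


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def extract_roi_means(values: np.ndarray, pixel_pitch: float,
                      rois: Iterable[ROI],
                      mask: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Mean map value inside each circular ROI.

    A map pixel (i, j) is centred at x = (j + 0.5) * pitch,
    y = (i + 0.5) * pitch; a pixel belongs to an ROI when its centre lies
    inside the circle.  ROIs covering zero valid pixels produce an error
    entry (``ok = False``) rather than raising.
    """
    values = np.asarray(values, dtype=float)
    h, w = values.shape
    ys = (np.arange(h) + 0.5) * pixel_pitch
    xs = (np.arange(w) + 0.5) * pixel_pitch
    valid = np.isfinite(values)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    rows = []
    for roi in rois:
        dy2 = (ys - roi.center_y) ** 2
        dx2 = (xs - roi.center_x) ** 2
        inside = dy2[:, None] + dx2[None, :] <= roi.radius ** 2
        sel = inside & valid
        npix = int(sel.sum())
        if npix == 0:
            rows.append({"roi_id": roi.roi_id, "mean": np.nan, "n_pixels": 0,
                         "ok": False, "error": "ROI covers no valid pixels"})
        else:
            rows.append({"roi_id": roi.roi_id, "mean": float(values[sel].mean()),
                         "n_pixels": npix, "ok": True, "error": ""})
    return pd.DataFrame(rows)


def build_roi_table(rois: Sequence[ROI], mu_s_means: pd.DataFrame,
                    od_means: pd.DataFrame, copa_means: pd.DataFrame,
                    extra: Optional[Mapping[str, pd.DataFrame]] = None) -> pd.DataFrame:
    """Assemble the per-ROI design table from per-map mean frames.

    ROIs with a failed extraction in any required map are dropped.
    ``extra`` adds optional response columns (e.g. mean_mu_b, mean_ratio).
    """
    table = pd.DataFrame({
        "roi_id": [r.roi_id for r in rois],
        "tissue_class": [r.tissue_class for r in rois],
        "layer": [r.layer for r in rois],
        "region": [r.region for r in rois],
    })
    for name, frame in [("mean_mu_s", mu_s_means), ("mean_od", od_means),
                        ("mean_copa", copa_means)] + list((extra or {}).items()):
        frame = frame.rename(columns={"mean": name})[["roi_id", name, "ok"]]
        table = table.merge(frame.rename(columns={"ok": f"_ok_{name}"}),
                            on="roi_id", how="left")
    ok_cols = [c for c in table.columns if c.startswith("_ok_")]
    keep = table[ok_cols].all(axis=1)
    return table.loc[keep].drop(columns=ok_cols).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Design matrix and fitting
# ---------------------------------------------------------------------------

def prepare_design(table: pd.DataFrame, model: str = "multivariate",
                   response: str = "mean_mu_s"):
    """Build (X, y, term_names) from an ROI table.

    X always carries an intercept column and the Gallyas OD column; the
    multivariate model adds COPA with white-matter entries forced to zero.
    """
    if model not in {"univariate", "multivariate"}:
        raise ValueError(f"unknown model {model!r}")
    required = ["mean_od", "tissue_class", response]
    if model == "multivariate":
        required.append("mean_copa")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"ROI table missing columns: {missing}")
    if table[required].isna().any().any():
        raise ValueError("ROI table contains missing values in fitted columns")

    n = len(table)
    cols = [np.ones(n), table["mean_od"].to_numpy(dtype=float)]
    names = ["intercept", "od"]
    if model == "multivariate":
        copa = table["mean_copa"].to_numpy(dtype=float).copy()
        copa[(table["tissue_class"] == "white").to_numpy()] = 0.0
        cols.append(copa)
        names.append("copa")
    X = np.column_stack(cols)
    if n < X.shape[1] + 1:
        raise ValueError(f"need at least {X.shape[1] + 1} ROIs, got {n}")
    y = table[response].to_numpy(dtype=float)
    return X, y, names


def fit_glm(X: np.ndarray, y: np.ndarray, model: str = "multivariate",
            term_names: Optional[Sequence[str]] = None) -> GLMFit:
    """Ordinary least squares with coefficient t-tests and fit diagnostics.

    Solves the pseudoinverse problem beta = (X^T X)^-1 X^T y via QR for
    numerical conditioning (identical to the normal-equations solution on
    full-rank designs).  Rank deficiency raises :class:`CollinearityError`
    naming the offending columns.  P-values are two-sided t-tests with
    n - p degrees of freedom; Bonferroni-corrected values (across the
    coefficients of the model) are reported alongside the raw ones.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if term_names is None:
        term_names = [f"x{i}" for i in range(p)]
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # columns whose removal restores full rank are the collinear ones
        bad = [term_names[j] for j in range(p)
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise CollinearityError(f"design matrix is rank deficient; "
                                f"collinear columns: {bad}")
    q, r = np.linalg.qr(X)
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
    rinv = np.linalg.inv(r)
    cov = sigma2 * (rinv @ rinv.T)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    p_corr = np.minimum(pvals * p, 1.0)

    r2, nrmse = goodness_of_fit(y, X @ beta)

    pcc = {}
    for j, name in enumerate(term_names):
        if name == "intercept":
            continue
        controls = np.delete(X, [0, j], axis=1)  # intercept handled internally
        try:
            pcc[name] = partial_correlation(y, X[:, j], controls)
        except UndefinedStatisticError:
            pcc[name] = np.nan
    return GLMFit(beta=beta, se=se, cov_beta=cov, p_values=pvals,
                  p_values_corrected=p_corr, r2=r2, nrmse=nrmse, n=n,
                  model=model, term_names=list(term_names), pcc=pcc)


def fit_roi_table(table: pd.DataFrame, model: str = "multivariate",
                  response: str = "mean_mu_s") -> GLMFit:
    """Convenience wrapper: prepare the design from a table and fit it."""
    X, y, names = prepare_design(table, model, response)
    return fit_glm(X, y, model=model, term_names=names)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def partial_correlation(y: np.ndarray, x: np.ndarray,
                        controls: Optional[np.ndarray] = None) -> float:
    """Pearson correlation of y and x after removing the controls' linear
    effect (with intercept) from both.

    With no controls this reduces to the plain Pearson correlation.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if controls is None or (hasattr(controls, "size") and np.size(controls) == 0):
        z = np.ones((n, 1))
    else:
        controls = np.asarray(controls, dtype=float)
        if controls.ndim == 1:
            controls = controls[:, None]
        z = np.column_stack((np.ones(n), controls))
    if n <= z.shape[1] + 1:
        raise ValueError("not enough observations for the requested controls")
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    sy, sx = np.linalg.norm(ry), np.linalg.norm(rx)
    # residuals of an exactly collinear input are numerical dust
    if sy <= 1e-10 * max(np.linalg.norm(y), 1.0) or \
            sx <= 1e-10 * max(np.linalg.norm(x), 1.0):
        raise UndefinedStatisticError("zero residual variance; PCC undefined")
    return float(np.clip(ry @ rx / (sy * sx), -1.0, 1.0))


def goodness_of_fit(y: np.ndarray, y_hat: np.ndarray) -> tuple[float, float]:
    """(R^2, NRMSE): squared Pearson correlation of (y, y_hat) and the RMSE
    normalised by range(y).

    Raises :class:`UndefinedStatisticError` when either input is constant,
    since the Pearson correlation is then undefined.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    if y.size < 2:
        raise ValueError("need at least two observations")
    if np.ptp(y) == 0 or np.ptp(y_hat) == 0:
        raise UndefinedStatisticError("constant input; correlation undefined")
    r = np.corrcoef(y, y_hat)[0, 1]
    rmse = float(np.sqrt(np.mean((y - y_hat) ** 2)))
    return float(r ** 2), rmse / float(np.ptp(y))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def compare_models(table: pd.DataFrame, response: str = "mean_mu_s") -> dict:
    """Side-by-side univariate vs multivariate fit of one ROI table.

    Reports k1, the OD correlation (plain Pearson for the univariate model,
    partial for the multivariate), R^2 and NRMSE per model, plus the
    relative k1 difference between the two.
    """
    uni = fit_roi_table(table, "univariate", response)
    multi = fit_roi_table(table, "multivariate", response)
    rel = abs(multi.k1 - uni.k1) / abs(uni.k1) if uni.k1 != 0 else np.nan
    return {
        "univariate": {"k1": uni.k1, "pcc_od": uni.pcc["od"],
                       "r2": uni.r2, "nrmse": uni.nrmse},
        "multivariate": {"k1": multi.k1, "pcc_od": multi.pcc["od"],
                         "r2": multi.r2, "nrmse": multi.nrmse},
        "k1_rel_difference": float(rel),
        "fits": {"univariate": uni, "multivariate": multi},
    }


def region_summaries(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-region (mean, SE) of white-matter mu_s and OD and grey-matter COPA.

    SE is sd / sqrt(n) over the ROI subset.  Empty subsets yield an error
    entry for that region instead of raising.
    """
    rows = []
    for region, table in tables.items():
        wm = table[table["tissue_class"] == "white"]
        gm = table[table["tissue_class"] == "grey"]
        row = {"region": region, "ok": True, "error": ""}
        if len(wm) < 2 or len(gm) < 2:
            rows.append({"region": region, "ok": False,
                         "error": "need >= 2 WM and >= 2 GM ROIs"})
            continue
        for name, sub, col in [("wm_mu_s", wm, "mean_mu_s"),
                               ("wm_od", wm, "mean_od"),
                               ("gm_copa", gm, "mean_copa")]:
            vals = sub[col].to_numpy(dtype=float)
            row[f"{name}_mean"] = float(vals.mean())
            row[f"{name}_se"] = float(vals.std(ddof=1) / np.sqrt(vals.size))
            row[f"{name}_n"] = int(vals.size)
        rows.append(row)
    return pd.DataFrame(rows)


def univariate_screens(table: pd.DataFrame) -> dict:
    """The four univariate back-scattering screens.

    Fits mu_b' and the mu_b'/mu_s ratio each as a linear function of Gallyas
    OD and of COPA (white-matter COPA zeroed), four separate univariate
    models in total.  No multivariate variant is fitted: the back-scattering
    quantities do not show strong joint structure.
    """
    fits = {}
    for response in ("mean_mu_b", "mean_ratio"):
        if response not in table.columns:
            raise ValueError(f"ROI table lacks response column {response!r}")
        for predictor in ("mean_od", "mean_copa"):
            x = table[predictor].to_numpy(dtype=float).copy()
            if predictor == "mean_copa":
                x[(table["tissue_class"] == "white").to_numpy()] = 0.0
            y = table[response].to_numpy(dtype=float)
            X = np.column_stack((np.ones(x.size), x))
            name = predictor.removeprefix("mean_")
            fits[f"{response.removeprefix('mean_')}_vs_{name}"] = fit_glm(
                X, y, model="univariate", term_names=["intercept", name])
    return fits


def fits_to_frame(fits: Mapping[str, GLMFit], region: str = "") -> pd.DataFrame:
    """Flatten named fits to one row per coefficient for CSV export."""
    rows = []
    for fit_name, fit in fits.items():
        dof = fit.n - len(fit.beta)
        for j, term in enumerate(fit.term_names):
            t = fit.beta[j] / fit.se[j] if fit.se[j] > 0 else np.nan
            rows.append({
                "region": region, "model": fit_name, "coefficient": term,
                "estimate": float(fit.beta[j]), "se": float(fit.se[j]),
                "t": float(t), "p": float(fit.p_values[j]),
                "p_corrected": float(fit.p_values_corrected[j]),
                "pcc": float(fit.pcc.get(term, np.nan)),
                "r2": float(fit.r2), "nrmse": float(fit.nrmse),
                "n": fit.n, "dof": dof,
            })
    return pd.DataFrame(rows)
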