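"""First-level GLM machinery.

Builds condition-level, parametric-modulation and single-trial design
matrices, fits ordinary-least-squares GLMs to masked time-series matrices,
and performs variance-inflation-factor (VIF) trial QC.

Conventions
-----------
* Task regressors are boxcars convolved with the canonical double-gamma HRF
  at a microtime resolution of 16 bins per TR (slice-reference bin 1).
* High-pass filtering is a DCT basis in the design (128-s cutoff) rather
  than pre-filtering, which keeps OLS exact.
* Six motion inputs are expanded to 24 nuisance columns: the parameters,
  their squares, their temporal derivatives and squared derivatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

MICROTIME_RESOLUTION = 16
MICROTIME_ONSET_BIN = 0  # slice-reference bin 1 (0-based index)
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_PEAK_DISP = 1.0
HRF_UNDERSHOOT_DISP = 1.0
HRF_RATIO = 6.0
HRF_LENGTH = 32.0


def _gamma_pdf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(
        (shape - 1) * np.log(tp) - tp / scale - gammaln(shape) - shape * np.log(scale)
    )
    return out


def hrf_values(times: np.ndarray) -> np.ndarray:
    """Canonical double-gamma HRF evaluated at arbitrary times (unit peak)."""
    times = np.asarray(times, dtype=float)
    main = _gamma_pdf(times, HRF_PEAK_DELAY / HRF_PEAK_DISP, HRF_PEAK_DISP)
    under = _gamma_pdf(
        times, HRF_UNDERSHOOT_DELAY / HRF_UNDERSHOOT_DISP, HRF_UNDERSHOOT_DISP
    )
    h = main - under / HRF_RATIO
    # unit peak normalization on a fine internal grid
    fine = np.arange(0, HRF_LENGTH, 0.01)
    fm = _gamma_pdf(fine, HRF_PEAK_DELAY / HRF_PEAK_DISP, HRF_PEAK_DISP)
    fu = _gamma_pdf(
        fine, HRF_UNDERSHOOT_DELAY / HRF_UNDERSHOOT_DISP, HRF_UNDERSHOOT_DISP
    )
    peak = (fm - fu / HRF_RATIO).max()
    return h / peak


def canonical_hrf(tr: float, duration: float = HRF_LENGTH) -> np.ndarray:
    """Sample the canonical double-gamma HRF on a TR grid.

    Peak delay 6 s, undershoot delay 16 s, dispersions 1, peak:undershoot
    ratio 6, kernel length 32 s, normalized to unit peak.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    times = np.arange(0, duration + 1e-9, tr)
    return hrf_values(times)


def convolve_boxcars(
    onsets: np.ndarray,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    tr: float,
    n_scans: int,
    oversampling: int = MICROTIME_RESOLUTION,
) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at scan times."""
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.broadcast_to(
        np.atleast_1d(np.asarray(durations, dtype=float)), onsets.shape
    )
    amplitudes = np.broadcast_to(
        np.atleast_1d(np.asarray(amplitudes, dtype=float)), onsets.shape
    )
    dt = tr / oversampling
    n_fine = n_scans * oversampling + int(np.ceil(HRF_LENGTH / dt))
    stick = np.zeros(n_fine)
    for on, du, am in zip(onsets, durations, amplitudes):
        i0 = int(np.round(on / dt))
        i1 = max(i0 + 1, int(np.round((on + du) / dt)))
        stick[i0:min(i1, n_fine)] += am
    kernel = hrf_values(np.arange(0, HRF_LENGTH + 1e-9, dt)) * dt
    conv = np.convolve(stick, kernel)[:n_fine]
    idx = np.arange(n_scans) * oversampling + MICROTIME_ONSET_BIN
    return conv[idx]


def dct_highpass_basis(n_scans: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """DCT drift basis for a high-pass cutoff; excludes the constant term.

    The column count follows the standard rule ``k = floor(2 * T / cutoff)``
    with ``T = n_scans * tr`` the run length in seconds.
    """
    n_scans = int(n_scans)
    order = int(np.floor(2.0 * n_scans * tr / cutoff))
    n = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * (2 * n + 1) * k / (2.0 * n_scans))
        for k in range(1, order + 1)
    ]
    if not cols:
        return np.empty((n_scans, 0))
    return np.column_stack(cols)


def motion_expansion(motion: np.ndarray) -> np.ndarray:
    """Expand 6 motion parameters to the 24-column nuisance block.

    Columns: the 6 parameters, their squares, their first temporal
    derivatives (backward difference, zero at the first scan) and the squared
    derivatives.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (n_scans, 6)")
    deriv = np.diff(motion, axis=0, prepend=motion[:1])
    return np.column_stack([motion, motion**2, deriv, deriv**2])


@dataclass
class DesignMatrix:
    """Named regressors with per-column roles.

    Roles are one of {"task", "modulator", "nuisance", "drift", "intercept"}.
    """

    frame: pd.DataFrame
    roles: dict[str, str]
    tr: float

    def __post_init__(self) -> None:
        if len(set(self.frame.columns)) != len(self.frame.columns):
            raise ValueError("design column names must be unique")
        unknown = set(self.frame.columns) - set(self.roles)
        if unknown:
            raise ValueError(f"columns without a role: {sorted(unknown)}")
        for name, role in self.roles.items():
            if role == "task" and np.allclose(self.frame[name].to_numpy(), 0):
                raise ValueError(f"task column {name!r} is all zero")
        if "intercept" not in set(self.roles.values()):
            raise ValueError("design must include an intercept column")

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def n_scans(self) -> int:
        return len(self.frame)

    def columns_with_role(self, *roles: str) -> list[str]:
        return [c for c in self.frame.columns if self.roles[c] in roles]

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _validate_events(events: pd.DataFrame, tr: float, n_scans: int) -> pd.DataFrame:
    events = events.reset_index(drop=True)
    for col in ("onset", "duration"):
        if col not in events:
            raise ValueError(f"events table needs an {col!r} column")
    end = events["onset"] + events["duration"]
    if (events["onset"] < 0).any() or (end > tr * n_scans + 1e-9).any():
        raise ValueError("event onsets/durations fall outside the scan window")
    return events


def _nuisance_columns(
    tr: float,
    n_scans: int,
    motion: np.ndarray | None,
    cutoff: float,
) -> tuple[pd.DataFrame, dict[str, str]]:
    cols: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    if motion is not None:
        block = motion_expansion(motion)
        for j in range(block.shape[1]):
            name = f"motion_{j:02d}"
            cols[name] = block[:, j]
            roles[name] = "nuisance"
    drift = dct_highpass_basis(n_scans, tr, cutoff)
    for j in range(drift.shape[1]):
        name = f"drift_{j + 1:02d}"
        cols[name] = drift[:, j]
        roles[name] = "drift"
    cols["intercept"] = np.ones(n_scans)
    roles["intercept"] = "intercept"
    return pd.DataFrame(cols), roles


def _report_column(
    events: pd.DataFrame, tr: float, n_scans: int
) -> np.ndarray | None:
    if "rating_onset" not in events:
        return None
    dur = events.get("rating_duration", pd.Series(2.0, index=events.index))
    return convolve_boxcars(
        events["rating_onset"].to_numpy(), np.asarray(dur, float), 1.0, tr, n_scans
    )


def build_condition_design(
    events: pd.DataFrame,
    tr: float,
    n_scans: int,
    motion: np.ndarray | None = None,
    cutoff: float = 128.0,
) -> DesignMatrix:
    """One HRF-convolved boxcar per observed rating level, plus nuisances.

    A rating level with no trials is simply absent.  If the events table has
    ``rating_onset`` (and optionally ``rating_duration``) columns, a single
    report-period regressor is added.
    """
    events = _validate_events(events, tr, n_scans)
    if "rating" not in events:
        raise ValueError("events table needs a 'rating' column")
    ratings = events["rating"].to_numpy()
    cols: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    for level in np.unique(ratings):
        sel = events[ratings == level]
        name = f"rating_level_{int(level)}"
        cols[name] = convolve_boxcars(
            sel["onset"].to_numpy(), sel["duration"].to_numpy(), 1.0, tr, n_scans
        )
        roles[name] = "task"
    report = _report_column(events, tr, n_scans)
    if report is not None:
        cols["report"], roles["report"] = report, "task"
    nuis, nroles = _nuisance_columns(tr, n_scans, motion, cutoff)
    frame = pd.concat([pd.DataFrame(cols), nuis], axis=1)
    roles.update(nroles)
    return DesignMatrix(frame=frame, roles=roles, tr=tr)


def build_parametric_design(
    events: pd.DataFrame,
    tr: float,
    n_scans: int,
    motion: np.ndarray | None = None,
    cutoff: float = 128.0,
    orthogonalize: bool = False,
) -> DesignMatrix:
    """Picture-period regressor plus a mean-centered rating modulator.

    Constant ratings annihilate the modulator after centering; the column is
    then dropped with a warning.  Orthogonalization of the modulator against
    the main picture regressor is off by default.
    """
    events = _validate_events(events, tr, n_scans)
    ratings = events["rating"].to_numpy(dtype=float)
    onsets = events["onset"].to_numpy()
    durations = events["duration"].to_numpy()
    cols: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    cols["picture"] = convolve_boxcars(onsets, durations, 1.0, tr, n_scans)
    roles["picture"] = "task"
    centered = ratings - ratings.mean()
    if np.allclose(centered, 0):
        warnings.warn(
            "ratings are constant; parametric modulator dropped", UserWarning
        )
    else:
        mod = convolve_boxcars(onsets, durations, centered, tr, n_scans)
        if orthogonalize:
            pic = cols["picture"]
            mod = mod - pic * (pic @ mod) / (pic @ pic)
        cols["modulation"] = mod
        roles["modulation"] = "modulator"
    report = _report_column(events, tr, n_scans)
    if report is not None:
        cols["report"], roles["report"] = report, "task"
    nuis, nroles = _nuisance_columns(tr, n_scans, motion, cutoff)
    frame = pd.concat([pd.DataFrame(cols), nuis], axis=1)
    roles.update(nroles)
    return DesignMatrix(frame=frame, roles=roles, tr=tr)


@dataclass
class GLMResult:
    """OLS estimates per design column, plus residual diagnostics."""

    betas: np.ndarray  # (n_columns, n_voxels)
    columns: list[str]
    residuals: np.ndarray  # (n_scans, n_voxels)
    sigma2: np.ndarray  # (n_voxels,)

    def beta(self, column: str) -> np.ndarray:
        return self.betas[self.columns.index(column)]


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(X)
    scale = np.abs(np.diag(r)).max() or 1.0
    bad = np.abs(np.diag(r)) < 1e-10 * scale
    return [names[j] for j in np.flatnonzero(bad)]


def fit_glm(Y: np.ndarray, design: DesignMatrix, check_rank: bool = True) -> GLMResult:
    """Fit an OLS GLM to a (scans x voxels) matrix.

    A rank-deficient design raises an error naming the collinear columns
    (unless ``check_rank`` is disabled, in which case a minimum-norm solution
    is returned, as used internally for single-trial QC paths).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != design.n_scans:
        raise ValueError("time-series rows must equal design rows")
    X = design.matrix
    names = list(design.frame.columns)
    if check_rank and np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise np.linalg.LinAlgError(
            f"design is rank deficient; collinear columns: {bad}"
        )
    betas, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ betas
    dof = max(Y.shape[0] - int(rank), 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    return GLMResult(betas=betas, columns=names, residuals=resid, sigma2=sigma2)


def compute_vif(design: DesignMatrix, targets: list[str] | None = None) -> pd.Series:
    """VIF per target column: 1 / (1 − R²) against all other non-intercept
    columns (an intercept is always included in the auxiliary regression).

    Perfect collinearity (R² = 1) is reported as ``+inf``.
    """
    X = design.frame
    if X.shape[1] < 2:
        raise ValueError("design needs at least 2 columns for VIF")
    non_intercept = design.columns_with_role("task", "modulator", "nuisance", "drift")
    if targets is None:
        targets = design.columns_with_role("task", "modulator")
    out = {}
    ones = np.ones((design.n_scans, 1))
    for name in targets:
        yj = X[name].to_numpy(dtype=float)
        others = [c for c in non_intercept if c != name]
        Z = np.column_stack([ones] + [X[c].to_numpy(dtype=float) for c in others])
        coef, _, _, _ = np.linalg.lstsq(Z, yj, rcond=None)
        ss_res = float(((yj - Z @ coef) ** 2).sum())
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot <= 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class TrialQCRecord:
    trial: int
    vif: float
    excluded: bool


def build_single_trial_design(
    events: pd.DataFrame,
    tr: float,
    n_scans: int,
    motion: np.ndarray | None = None,
    cutoff: float = 128.0,
) -> DesignMatrix:
    """LSA design: one regressor per trial plus the shared nuisance block."""
    events = _validate_events(events, tr, n_scans)
    cols: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    for i, row in events.iterrows():
        name = f"trial_{i:04d}"
        cols[name] = convolve_boxcars(row["onset"], row["duration"], 1.0, tr, n_scans)
        roles[name] = "task"
    report = _report_column(events, tr, n_scans)
    if report is not None:
        cols["report"], roles["report"] = report, "task"
    nuis, nroles = _nuisance_columns(tr, n_scans, motion, cutoff)
    frame = pd.concat([pd.DataFrame(cols), nuis], axis=1)
    roles.update(nroles)
    return DesignMatrix(frame=frame, roles=roles, tr=tr)


def estimate_single_trial_betas(
    Y: np.ndarray,
    events: pd.DataFrame,
    tr: float,
    motion: np.ndarray | None = None,
    mode: str = "LSA",
    vif_threshold: float = 3.0,
    cutoff: float = 128.0,
    subject_id: str = "sub-01",
):
    """Single-trial beta maps with VIF-based QC.

    LSA fits one GLM with a regressor per trial; LSS fits one GLM per trial
    with a target regressor versus an all-other-trials regressor.  Both
    modes share the nuisance/drift construction, and trial VIFs are computed
    on the LSA design in both cases (QC is a property of the joint layout).
    Trials with VIF above ``vif_threshold`` are marked excluded but their
    betas are still returned; filter with :func:`apply_trial_qc`.
    """
    from .datasets import BetaImageSet

    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    events = _validate_events(events, tr, Y.shape[0])
    n_scans = Y.shape[0]
    lsa = build_single_trial_design(events, tr, n_scans, motion, cutoff)
    trial_cols = [c for c in lsa.frame.columns if c.startswith("trial_")]
    if mode.upper() == "LSA" and n_scans < lsa.frame.shape[1]:
        raise ValueError(
            f"LSA design has {lsa.frame.shape[1]} columns but only {n_scans} "
            "scans; use mode='LSS'"
        )
    vifs = compute_vif(lsa, targets=trial_cols)
    qc = [
        TrialQCRecord(trial=i, vif=float(vifs.iloc[i]),
                      excluded=bool(vifs.iloc[i] > vif_threshold))
        for i in range(len(trial_cols))
    ]

    n_trials = len(trial_cols)
    if mode.upper() == "LSA":
        fit = fit_glm(Y, lsa, check_rank=False)
        betas = np.stack([fit.beta(c) for c in trial_cols])
    elif mode.upper() == "LSS":
        betas = np.empty((n_trials, Y.shape[1]))
        onsets = events["onset"].to_numpy()
        durations = events["duration"].to_numpy()
        nuis, nroles = _nuisance_columns(tr, n_scans, motion, cutoff)
        report = _report_column(events, tr, n_scans)
        for i in range(n_trials):
            cols = {
                "target": convolve_boxcars(
                    onsets[i], durations[i], 1.0, tr, n_scans
                )
            }
            roles = {"target": "task"}
            others = np.arange(n_trials) != i
            if others.any():
                cols["others"] = convolve_boxcars(
                    onsets[others], durations[others], 1.0, tr, n_scans
                )
                roles["others"] = "task"
            if report is not None:
                cols["report"], roles["report"] = report, "task"
            frame = pd.concat([pd.DataFrame(cols), nuis], axis=1)
            roles.update(nroles)
            design = DesignMatrix(frame=frame, roles=roles, tr=tr)
            betas[i] = fit_glm(Y, design, check_rank=False).beta("target")
    else:
        raise ValueError("mode must be 'LSA' or 'LSS'")

    trial_set = BetaImageSet(
        data=betas,
        subject_ids=np.repeat(subject_id, n_trials),
        ratings=events["rating"].to_numpy(dtype=float) if "rating" in events else
        np.full(n_trials, np.nan),
        level="trial",
    )
    return trial_set, qc


def apply_trial_qc(trial_set, qc: list[TrialQCRecord]):
    """Drop excluded trials from a single-subject trial beta set."""
    keep = np.array([not r.excluded for r in qc])
    return trial_set.subset_obs(np.flatnonzero(keep))


def qc_table(qc: list[TrialQCRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial": [r.trial for r in qc],
            "vif": [r.vif for r in qc],
            "excluded": [r.excluded for r in qc],
        }
    )
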