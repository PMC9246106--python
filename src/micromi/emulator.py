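"""Fast emulation of the simulator's parameter-to-rate mapping.

The default backend regresses each calibration output on a full
quadratic expansion (main effects, squares, pairwise interactions) of
the parameters, standardised to [-1, 1] over the design box.  Predictive
variance is the residual variance inflated by the hat-matrix leverage
term, so it grows away from the training design.  Because training runs
are stochastic simulations, the residual variance also absorbs their
Monte-Carlo noise.  A Gaussian-process backend (scikit-learn) can be
selected where the extra flexibility is worth the fit cost.

Per-output held-out correlations between emulated and simulated
responses are stored as diagnostics; downstream screening can exclude
poorly emulated outputs.
"""

from __future__ import annotations

import json
import tarfile
import warnings
from dataclasses import dataclass, field
from io import BytesIO

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = ["latin_hypercube", "TrainingSet", "EmulatorModel", "fit_emulator"]


def latin_hypercube(n: int, priors: dict[str, tuple[float, float]],
                    seed: int = 0) -> pd.DataFrame:
    """Space-filling design over the prior box: each margin has exactly
    one point per 1/n stratum.  Degenerate ranges (lower == upper) yield
    a constant column with a warning.  Deterministic given ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    names = list(priors)
    lo = np.array([priors[k][0] for k in names], float)
    hi = np.array([priors[k][1] for k in names], float)
    if not (np.isfinite(lo).all() and np.isfinite(hi).all()):
        raise ValueError("prior ranges must be finite")
    degenerate = hi == lo
    if degenerate.any():
        warnings.warn("degenerate prior range(s): "
                      + ", ".join(np.array(names)[degenerate]),
                      stacklevel=2)
    from scipy.stats import qmc
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    return pd.DataFrame(lo + unit * (hi - lo), columns=names)


@dataclass
class TrainingSet:
    """Paired design (parameter vectors) and responses (calibration
    outputs), one row per simulator run."""

    design: pd.DataFrame
    responses: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.design) != len(self.responses):
            raise ValueError("design and responses must have matching row counts")
        if self.responses.isna().any().any():
            bad = self.responses.columns[self.responses.isna().any()].tolist()
            raise ValueError(f"responses contain missing values in columns {bad}")

    def save(self, design_path: str, responses_path: str) -> None:
        d = self.design.copy()
        d.insert(0, "run_id", range(len(d)))
        r = self.responses.copy()
        r.insert(0, "run_id", range(len(r)))
        d.to_csv(design_path, index=False)
        r.to_csv(responses_path, index=False)

    @classmethod
    def load(cls, design_path: str, responses_path: str) -> "TrainingSet":
        d = pd.read_csv(design_path)
        r = pd.read_csv(responses_path)
        merged = d.merge(r, on="run_id", suffixes=("", "_resp"))
        return cls(design=merged[d.columns.drop("run_id")],
                   responses=merged[r.columns.drop("run_id")])


def _quadratic_features(z: np.ndarray) -> np.ndarray:
    """[1, z_i, z_i^2, z_i z_j (i<j)] feature expansion."""
    n, d = z.shape
    iu, ju = np.triu_indices(d, k=1)
    return np.hstack([np.ones((n, 1)), z, z ** 2, z[:, iu] * z[:, ju]])


def _feature_names(names: list[str]) -> list[str]:
    d = len(names)
    iu, ju = np.triu_indices(d, k=1)
    return (["1"] + names + [f"{k}^2" for k in names]
            + [f"{names[i]}*{names[j]}" for i, j in zip(iu, ju)])


@dataclass
class EmulatorModel:
    """Per-output predictor with mean and variance over parameter space."""

    backend: str
    param_names: list[str]
    output_names: list[str]
    box_lo: np.ndarray
    box_hi: np.ndarray
    diagnostics: pd.Series            # held-out correlation per output
    coef: np.ndarray | None = field(default=None, repr=False)     # (p, k)
    sigma2: np.ndarray | None = field(default=None, repr=False)   # (k,)
    xtx_cho: np.ndarray | None = field(default=None, repr=False)  # chol(X'X)
    gps: list | None = field(default=None, repr=False)

    def _standardise(self, thetas: pd.DataFrame) -> np.ndarray:
        x = thetas[self.param_names].to_numpy(float)
        span = self.box_hi - self.box_lo
        tol = 1e-9 * np.maximum(np.abs(span), 1.0)
        if ((x < self.box_lo - tol) | (x > self.box_hi + tol)).any():
            raise ValueError("parameter vector outside the training box; "
                             "the emulator does not extrapolate")
        safe = np.where(span > 0, span, 1.0)
        return 2.0 * (x - self.box_lo) / safe - 1.0

    def predict(self, thetas: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Predictive mean and variance per output at each parameter
        vector; vectorised over rows."""
        z = self._standardise(thetas)
        if self.backend == "quadratic":
            F = _quadratic_features(z)
            mean = F @ self.coef
            # leverage term of the prediction variance
            w = linalg.solve_triangular(self.xtx_cho, F.T, lower=True)
            q = np.einsum("ij,ij->j", w, w)
            var = self.sigma2[None, :] * (1.0 + q)[:, None]
        else:
            means, vars_ = [], []
            for gp in self.gps:
                m, s = gp.predict(z, return_std=True)
                means.append(m)
                vars_.append(s ** 2)
            mean = np.column_stack(means)
            var = np.column_stack(vars_)
        cols = self.output_names
        return (pd.DataFrame(mean, columns=cols), pd.DataFrame(var, columns=cols))

    def save(self, path: str) -> None:
        manifest = {"backend": self.backend, "param_names": self.param_names,
                    "output_names": self.output_names,
                    "diagnostics": self.diagnostics.to_dict()}
        arrays = {"box_lo": self.box_lo, "box_hi": self.box_hi}
        if self.backend == "quadratic":
            arrays.update(coef=self.coef, sigma2=self.sigma2, xtx_cho=self.xtx_cho)
        with tarfile.open(path, "w") as tar:
            mb = json.dumps(manifest).encode()
            info = tarfile.TarInfo("manifest.json")
            info.size = len(mb)
            tar.addfile(info, BytesIO(mb))
            buf = BytesIO()
            np.savez(buf, **arrays)
            info = tarfile.TarInfo("arrays.npz")
            info.size = buf.getbuffer().nbytes
            buf.seek(0)
            tar.addfile(info, buf)

    @classmethod
    def load(cls, path: str) -> "EmulatorModel":
        with tarfile.open(path) as tar:
            manifest = json.load(tar.extractfile("manifest.json"))
            arrays = np.load(BytesIO(tar.extractfile("arrays.npz").read()))
            if manifest["backend"] != "quadratic":
                raise NotImplementedError("only quadratic models round-trip to disk")
            return cls(backend="quadratic",
                       param_names=manifest["param_names"],
                       output_names=manifest["output_names"],
                       box_lo=arrays["box_lo"], box_hi=arrays["box_hi"],
                       diagnostics=pd.Series(manifest["diagnostics"]),
                       coef=arrays["coef"], sigma2=arrays["sigma2"],
                       xtx_cho=arrays["xtx_cho"])


def fit_emulator(training: TrainingSet, holdout_fraction: float = 0.2,
                 backend: str = "quadratic", seed: int = 0,
                 box: dict[str, tuple[float, float]] | None = None) -> EmulatorModel:
    """Fit one predictor per calibration output.

    A random ``holdout_fraction`` of runs is withheld to score each
    output (Pearson correlation between emulated and simulated values);
    the returned model is then refit on all rows.  ``box`` fixes the
    standardisation region and the no-extrapolation boundary (default:
    the design's min/max per column — pass the prior box when predictions
    over the whole prior space are needed).  Parameter columns constant
    over the box are dropped from the basis.  A design whose quadratic
    basis is rank-deficient raises an error naming the collinear terms.
    """
    X = training.design
    Y = training.responses.to_numpy(float)
    n = len(X)
    if box is not None:
        box_lo = np.array([box[c][0] for c in X.columns], float)
        box_hi = np.array([box[c][1] for c in X.columns], float)
    else:
        box_lo = X.min().to_numpy(float)
        box_hi = X.max().to_numpy(float)
    active = box_hi > box_lo
    names = [c for c, a in zip(X.columns, active) if a]
    if not names:
        raise ValueError("all parameter columns are constant; nothing to emulate")

    model = EmulatorModel(backend=backend, param_names=names,
                          output_names=list(training.responses.columns),
                          box_lo=box_lo[active], box_hi=box_hi[active],
                          diagnostics=pd.Series(dtype=float))
    z = model._standardise(X)

    if backend == "quadratic":
        F = _quadratic_features(z)
        p = F.shape[1]
        if n < 10 * len(names):
            warnings.warn(f"only {n} training rows for {len(names)} parameters; "
                          "at least 10x is recommended", stacklevel=2)
        rank = np.linalg.matrix_rank(F)
        if rank < p:
            _, _, piv = linalg.qr(F, mode="economic", pivoting=True)
            feat = _feature_names(names)
            bad = sorted(feat[i] for i in piv[rank:])
            raise ValueError(f"singular quadratic design (rank {rank} < {p}); "
                             f"collinear terms: {bad}")
        fit_fn = lambda Ftr, Ytr: np.linalg.lstsq(Ftr, Ytr, rcond=None)[0]
    elif backend != "gp":
        raise ValueError(f"unknown backend {backend!r}")

    # held-out diagnostic
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_hold = int(round(holdout_fraction * n))
    hold, train = perm[:n_hold], perm[n_hold:]
    if n_hold >= 2 and len(train) >= 2:
        if backend == "quadratic":
            beta = fit_fn(F[train], Y[train])
            pred_hold = F[hold] @ beta
        else:
            pred_hold = np.column_stack(
                [_fit_gp(z[train], Y[train, k]).predict(z[hold])
                 for k in range(Y.shape[1])])
        diag = _columnwise_corr(pred_hold, Y[hold])
    else:
        warnings.warn("holdout too small for diagnostics; storing NaN",
                      stacklevel=2)
        diag = np.full(Y.shape[1], np.nan)
    model.diagnostics = pd.Series(diag, index=model.output_names)

    # final fit on all rows
    if backend == "quadratic":
        model.coef = fit_fn(F, Y)
        resid = Y - F @ model.coef
        dof = max(n - p, 1)
        model.sigma2 = (resid ** 2).sum(axis=0) / dof
        model.xtx_cho = linalg.cholesky(F.T @ F + 1e-10 * np.eye(p), lower=True)
    else:
        model.gps = [_fit_gp(z, Y[:, k]) for k in range(Y.shape[1])]
    return model


def _fit_gp(z: np.ndarray, y: np.ndarray):
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
    kernel = (ConstantKernel(1.0, (1e-3, 1e4)) * RBF(1.0, (1e-2, 1e2))
              + WhiteKernel(1e-2, (1e-8, 1e2)))
    gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                  n_restarts_optimizer=1, random_state=0)
    return gp.fit(z, y)


def _columnwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    denom = np.sqrt((a ** 2).sum(axis=0) * (b ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / denom
    return np.where(denom > 0, r, 0.0)
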