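"""Non-negative sparse coding by the locally competitive algorithm (LCA).

Hippocampal model cells are leaky integrators competing through the
dictionary-derived lateral weights W = A^T A - I:

    tau du/dt = -u + A^T I - W s,    s = max(u - beta, 0),

and the feedforward dictionary A (non-negative, unit-norm columns) learns
by the Hebbian residual rule dA = eta (I - A s) s^T, clipped at zero and
column-renormalised after every trajectory step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import lca_steps, run_session

__all__ = ["SparseCodingModel", "ModelState", "init_model",
           "lca_infer", "update_weights", "inactivate_inputs",
           "save_model", "load_model"]


@dataclass
class ModelState:
    """Membrane potentials and firing rates of the model cells."""

    u: np.ndarray
    s: np.ndarray

    @classmethod
    def zeros(cls, n_cells: int) -> "ModelState":
        return cls(np.zeros(n_cells), np.zeros(n_cells))


@dataclass
class SparseCodingModel:
    """Dictionary plus LCA dynamics constants.

    tau is the membrane time constant (10 ms), beta the firing threshold
    (0.3), dt_model the Euler step (0.2 ms, so dt/tau = 0.02), n_inner the
    number of LCA iterations per 10 ms trajectory step (50) and eta the
    learning rate (0.01).
    """

    A: np.ndarray                  # (n_inputs, n_cells), >= 0, unit columns
    tau: float = 0.010
    beta: float = 0.3
    dt_model: float = 0.0002
    n_inner: int = 50
    eta: float = 0.01
    learning_enabled: bool = True
    degenerate_columns: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_inputs(self) -> int:
        return self.A.shape[0]

    @property
    def n_cells(self) -> int:
        return self.A.shape[1]

    @property
    def dt_over_tau(self) -> float:
        return self.dt_model / self.tau

    def lateral_weights(self) -> np.ndarray:
        """W = A^T A - I, always derived from the current dictionary."""
        return self.A.T @ self.A - np.eye(self.n_cells)

    def copy(self) -> "SparseCodingModel":
        return replace(self, A=self.A.copy())


def init_model(n_inputs: int, n_cells: int, seed=None,
               **kwargs) -> SparseCodingModel:
    """Dictionary initialised U(0,1) entrywise, columns normalised to
    unit Euclidean norm."""
    if n_inputs <= 0 or n_cells <= 0:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    A = rng.uniform(0.0, 1.0, size=(n_inputs, n_cells))
    A /= np.linalg.norm(A, axis=0)
    return SparseCodingModel(A=A, **kwargs)


def lca_infer(model: SparseCodingModel, I, state: ModelState | None = None,
              n_iter: int | None = None) -> ModelState:
    """Run ``n_iter`` (default ``model.n_inner``) forward-Euler LCA steps
    from ``state`` (zeros if omitted) and return the updated state.

    The state is carried over between successive trajectory steps of a
    session; it is reset only at session start.
    """
    I = np.ascontiguousarray(I, dtype=np.float64)
    if I.shape != (model.n_inputs,):
        raise ValueError(f"input length {I.shape} != {model.n_inputs}")
    if state is None:
        state = ModelState.zeros(model.n_cells)
    u = state.u.astype(np.float64).copy()
    s = np.maximum(u - model.beta, 0.0)
    b = I @ model.A
    lca_steps(np.ascontiguousarray(model.A), b, u, s,
              n_iter or model.n_inner, model.dt_over_tau, model.beta)
    if not np.all(np.isfinite(u)):
        raise FloatingPointError("LCA dynamics diverged (non-finite u)")
    return ModelState(u, s)


def update_weights(model: SparseCodingModel, I, s) -> SparseCodingModel:
    """One Hebbian update dA = eta (I - A s) s^T, in place: negative
    entries clipped, touched columns renormalised to unit norm."""
    if not model.learning_enabled:
        return model
    I = np.asarray(I, dtype=float)
    s = np.asarray(s, dtype=float)
    resid = I - model.A @ s
    active = np.nonzero(s > 0)[0]
    if active.size:
        block = model.A[:, active] + model.eta * np.outer(resid, s[active])
        np.clip(block, 0.0, None, out=block)
        norms = np.linalg.norm(block, axis=0)
        nz = norms > 0
        block[:, nz] /= norms[nz]
        model.A[:, active] = block
    return model


def inactivate_inputs(model: SparseCodingModel,
                      row_indices) -> SparseCodingModel:
    """Zero the given input rows of A, renormalise columns, and disable
    learning (lesion experiment).  Columns left entirely zero are
    reported in ``degenerate_columns`` and kept at zero."""
    rows = np.asarray(row_indices, dtype=int)
    if rows.size and (rows.min() < 0 or rows.max() >= model.n_inputs):
        raise IndexError("row indices out of range")
    out = model.copy()
    out.A[rows, :] = 0.0
    norms = np.linalg.norm(out.A, axis=0)
    dead = np.nonzero(norms == 0)[0]
    live = norms > 0
    out.A[:, live] /= norms[live]
    out.learning_enabled = False
    out.degenerate_columns = dead
    return out


def run_section(model: SparseCodingModel, I_block, state: ModelState,
                learn: bool | None = None):
    """Advance the model over a block of trajectory steps.

    I_block is (steps, n_inputs); returns (S, err) with the settled rates
    per step and the squared reconstruction error ||I - A s||^2.  The
    dictionary is updated in place when learning is on.
    """
    I_block = np.ascontiguousarray(I_block, dtype=np.float64)
    S = np.empty((I_block.shape[0], model.n_cells))
    err = np.empty(I_block.shape[0])
    do_learn = model.learning_enabled if learn is None else learn
    run_session(model.A, I_block, state.u, state.s, model.n_inner,
                model.dt_over_tau, model.beta, model.eta, do_learn, S, err)
    if not np.all(np.isfinite(state.u)):
        raise FloatingPointError("LCA dynamics diverged (non-finite u)")
    return S, err


def save_model(model: SparseCodingModel, path) -> None:
    np.savez_compressed(
        path, A=model.A,
        hyper=np.array([model.tau, model.beta, model.dt_model,
                        model.n_inner, model.eta,
                        float(model.learning_enabled)]),
        degenerate=model.degenerate_columns)


def load_model(path) -> SparseCodingModel:
    with np.load(path) as z:
        A = z["A"]
        h = z["hyper"]
        degenerate = z["degenerate"].astype(int)
    return SparseCodingModel(A=A, tau=h[0], beta=h[1], dt_model=h[2],
                             n_inner=int(h[3]), eta=h[4],
                             learning_enabled=bool(h[5]),
                             degenerate_columns=degenerate)
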