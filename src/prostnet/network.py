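"""Six-node gene-regulatory network model of AR/NF-κB crosstalk.

The model describes the activities :math:`x_i(t)` of six signalling nodes
in prostate epithelial cells — AR, PI3K, PTEN, p65 NF-κB, IκB and c-Myc —
with "almost linear" dynamics

.. math::

    \\frac{dx_i}{dt} = J_i - d_i x_i + \\sum_j A_{ij} x_j + \\sigma_i,

subject to the positivity condition :math:`x_i \\ge 0`.  ``J`` is the base
production of each node, ``d`` its first-order decay rate and ``A`` the
signed interaction matrix (row = target, column = source).  The only
nonlinearity is the clamp at zero, so the unperturbed system has a unique
fixed point obtained from a linear solve, and stability is read off the
spectrum of ``A - diag(d)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkModel",
    "FixedPointResult",
    "ar_nfkb_model",
    "fixed_point",
    "scale_transform",
    "CONDITION_NUMBER_LIMIT",
]

# Systems with a steady-state matrix worse conditioned than this are
# rejected: the fixed point would not be numerically meaningful.
CONDITION_NUMBER_LIMIT = 1e12


@dataclass(frozen=True)
class NetworkModel:
    """A linear-plus-positivity regulatory network.

    Parameters
    ----------
    labels
        Ordered, unique node names.
    J
        Base production per node (activity · time⁻¹).  Entries may be
        negative: a node can have net basal repression.
    d
        First-order decay rate per node (time⁻¹); strictly positive.
    A
        Interaction matrix (time⁻¹).  ``A[i, j]`` is the effect of the
        activity of source node ``j`` on the rate of change of target
        node ``i``; positive entries activate, negative inhibit.
    """

    labels: tuple[str, ...]
    J: np.ndarray
    d: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        for name in ("J", "d", "A"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("node labels must be unique")
        if self.J.shape != (n,):
            raise ValueError(f"J has shape {self.J.shape}, expected ({n},)")
        if self.d.shape != (n,):
            raise ValueError(f"d has shape {self.d.shape}, expected ({n},)")
        if self.A.shape != (n, n):
            raise ValueError(f"A has shape {self.A.shape}, expected ({n}, {n})")
        for name in ("J", "d", "A"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite entries")
        if not np.all(self.d > 0):
            raise ValueError("all decay rates d must be strictly positive")

    @property
    def n(self) -> int:
        return len(self.labels)

    def node_index(self, node: int | str) -> int:
        """Resolve a node given by label or integer index."""
        if isinstance(node, str):
            try:
                return self.labels.index(node)
            except ValueError:
                raise KeyError(
                    f"unknown node {node!r}; known labels: {list(self.labels)}"
                ) from None
        i = int(node)
        if not 0 <= i < self.n:
            raise KeyError(f"node index {i} out of range for {self.n}-node model")
        return i


@dataclass(frozen=True)
class FixedPointResult:
    """Steady state and local stability of a :class:`NetworkModel`.

    ``x_star`` solves ``(diag(d) - A) x = J`` (the zero-noise steady state);
    ``eigenvalues`` is the spectrum of the Jacobian ``A - diag(d)``;
    ``stable`` means every eigenvalue has negative real part; ``feasible``
    means every steady-state activity is strictly positive, i.e. the fixed
    point lies in the interior where the positivity clamp is inactive.
    """

    x_star: np.ndarray
    eigenvalues: np.ndarray
    stable: bool
    feasible: bool
    condition_number: float = field(default=float("nan"))


def ar_nfkb_model() -> NetworkModel:
    """The default six-node AR/PI3K/PTEN/p65/IκB/c-Myc crosstalk model.

    Encodes the experimentally motivated links: AR represses p65; PI3K
    activates p65, PTEN and c-Myc; PTEN inhibits PI3K; p65 induces its own
    inhibitor IκB (the NF-κB negative feedback loop) as well as AR, PI3K
    and c-Myc; IκB inhibits p65; c-Myc feeds back positively on AR and
    negatively on PI3K.  All decay rates are equal — the proteins are taken
    to degrade at approximately the same rate.
    """
    labels = ("AR", "PI3K", "PTEN", "p65", "IkB", "cMyc")
    J = [1.5, 2.0, -0.1, 2.0, -0.1, 0.8]
    d = [1.0] * 6
    A = [
        [0.0, -1.0, 0.0, 0.5, 0.0, 0.7],   # AR
        [0.0, 0.0, -2.0, 1.0, 0.0, -0.5],  # PI3K
        [0.0, 2.0, 0.0, 0.0, 0.0, 0.0],    # PTEN
        [-0.9, 1.5, 0.0, 0.0, -3.0, 0.5],  # p65
        [0.0, 0.0, 0.0, 3.0, 0.0, 0.0],    # IkB
        [0.0, 0.5, 0.0, 1.0, 0.0, 0.0],    # cMyc
    ]
    return NetworkModel(labels=labels, J=J, d=d, A=A)


def fixed_point(
    model: NetworkModel, cond_limit: float = CONDITION_NUMBER_LIMIT
) -> FixedPointResult:
    """Solve for the zero-noise steady state and classify its stability.

    Sets the rate in the governing equation to zero and solves the linear
    system ``(diag(d) - A) x* = J``.  Raises :class:`ValueError` when the
    steady-state matrix is singular or has condition number above
    ``cond_limit`` (no unique fixed point).
    """
    M = np.diag(model.d) - model.A
    cond = float(np.linalg.cond(M))
    if not np.isfinite(cond) or cond > cond_limit:
        raise ValueError(
            "no unique fixed point: steady-state matrix diag(d) - A is "
            f"singular or ill-conditioned (condition number {cond:.3g} "
            f"exceeds {cond_limit:.3g})"
        )
    x_star = np.linalg.solve(M, model.J)
    eigenvalues = np.linalg.eigvals(model.A - np.diag(model.d))
    return FixedPointResult(
        x_star=x_star,
        eigenvalues=eigenvalues,
        stable=bool(np.all(eigenvalues.real < 0)),
        feasible=bool(np.min(x_star) > 0),
        condition_number=cond,
    )


def scale_transform(model: NetworkModel, lam) -> NetworkModel:
    """Rescale node activities to ``y_i(t) = λ_i x_i(t)``.

    The transformed parameters are ``J'_i = λ_i J_i`` and
    ``A'_ij = λ_i A_ij / λ_j`` with the decay rates unchanged; substituting
    ``y = λ∘x`` into the dynamics shows this is the unique choice for which
    the scaled system reproduces the original trajectories exactly
    (diagonal entries of ``A`` are invariant).  Each ``λ_i`` must be
    strictly positive.
    """
    lam = np.asarray(lam, dtype=float)
    if lam.shape != (model.n,):
        raise ValueError(f"lam has shape {lam.shape}, expected ({model.n},)")
    if not np.all(np.isfinite(lam)) or not np.all(lam > 0):
        raise ValueError("all scale factors must be finite and strictly positive")
    return NetworkModel(
        labels=model.labels,
        J=lam * model.J,
        d=model.d.copy(),
        A=lam[:, None] * model.A / lam[None, :],
    )
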