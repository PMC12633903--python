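"""Cross-Modal Fusion (CMF): combine two single-modal predictions.

Two modality-level predictions for the same patient — labels ``rho_a``,
``rho_b``, positive-class probabilities ``eta_a``, ``eta_b``, and the
models' held-out accuracies ``phi_a``, ``phi_b`` — are fused through three
quantities:

* category difference   ``Omega = rho_a - rho_b``  (in {-1, 0, 1}),
* accuracy difference   ``sigma = phi_a - phi_b``  (only its sign branches),
* probability difference ``upsilon = eta_a - eta_b``.

Decision branches:

A. *Agreement* (Omega = 0): keep the common label; the fused probability is
   the accuracy-weighted mean ``(phi_a eta_a + phi_b eta_b)/(phi_a+phi_b)``
   (plain mean if both accuracies are zero). Applying the logistic
   adjustment here would squash every agreed probability into a narrow band
   around iota/2 and destroy calibration, so it is reserved for conflicts.

B. *Disagreement, sigma != 0*: trust the more accurate modality for the
   label; its confidence edge over the other feeds the logistic adjustment
   ``eta_new = iota / (1 + exp(-alpha * (eta_chosen - eta_other)))`` with
   alpha = 0.4, iota = 1 by default.

C. *Disagreement, sigma = 0*: choose the modality whose probability sits
   further from the threshold (larger |eta - t|); at an exact confidence
   tie, the prediction with the larger eta (and at equal eta the positive
   label) — a tie-break that does not depend on argument order, so fusion
   is commutative. Then proceed as in B.

Orienting the logistic input as eta_chosen - eta_other (rather than the raw
upsilon) makes the fused probability and fused label provably consistent
under the strict threshold rule for threshold-consistent inputs; the raw
upsilon is still reported in :class:`FusionTerms` exactly as defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .learners import SingleModalPrediction

__all__ = [
    "FusionParams",
    "FusionTerms",
    "FusedPrediction",
    "ModalPrediction",
    "fusion_terms",
    "sigmoid_adjust",
    "cmf_fuse",
    "fuse_batch",
]

Branch = Literal["agreement", "accuracy", "confidence-tiebreak"]


@dataclass(frozen=True)
class FusionParams:
    """Logistic-adjustment parameters: steepness alpha, ceiling iota, threshold t."""

    alpha: float = 0.4
    iota: float = 1.0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not (0.0 < self.iota <= 1.0):
            raise ValueError("iota must lie in (0, 1]")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie strictly in (0, 1)")


@dataclass(frozen=True)
class FusionTerms:
    """The three fusion intermediates, exactly as defined."""

    omega: int
    sigma: float
    upsilon: float


@dataclass(frozen=True)
class FusedPrediction:
    """Fused output Phi = [rho, eta] plus the branch taken, for audit."""

    rho: int
    eta: float
    branch: Branch


@dataclass(frozen=True)
class ModalPrediction:
    """One patient's (rho, eta, phi) triplet — the unit the rule fuses."""

    rho: int
    eta: float
    phi: float


def fusion_terms(pred_a: ModalPrediction, pred_b: ModalPrediction) -> FusionTerms:
    """Omega, sigma, upsilon for one patient's pair of predictions."""
    for name, p in (("a", pred_a), ("b", pred_b)):
        if p.phi is None:
            raise ValueError(f"prediction {name} lacks an accuracy phi; fusion needs it")
    return FusionTerms(
        omega=int(pred_a.rho) - int(pred_b.rho),
        sigma=float(pred_a.phi) - float(pred_b.phi),
        upsilon=float(pred_a.eta) - float(pred_b.eta),
    )


def sigmoid_adjust(upsilon: float, params: FusionParams = FusionParams()) -> float:
    """Logistic probability adjustment iota / (1 + exp(-alpha * upsilon))."""
    return params.iota / (1.0 + np.exp(-params.alpha * upsilon))


def _resolve_disagreement(
    pred_a: ModalPrediction, pred_b: ModalPrediction, params: FusionParams, branch: Branch
) -> FusedPrediction:
    if branch == "accuracy":
        chosen, other = (pred_a, pred_b) if pred_a.phi > pred_b.phi else (pred_b, pred_a)
    else:
        conf_a = abs(pred_a.eta - params.threshold)
        conf_b = abs(pred_b.eta - params.threshold)
        if conf_a != conf_b:
            chosen, other = (pred_a, pred_b) if conf_a > conf_b else (pred_b, pred_a)
        elif pred_a.eta != pred_b.eta:
            chosen, other = (pred_a, pred_b) if pred_a.eta > pred_b.eta else (pred_b, pred_a)
        else:
            # equal eta, equal confidence, different labels: prefer progression
            chosen, other = (pred_a, pred_b) if pred_a.rho >= pred_b.rho else (pred_b, pred_a)
    eta = sigmoid_adjust(chosen.eta - other.eta, params)
    return FusedPrediction(rho=int(chosen.rho), eta=float(eta), branch=branch)


def cmf_fuse(
    pred_a: ModalPrediction, pred_b: ModalPrediction, params: FusionParams = FusionParams()
) -> FusedPrediction:
    """Fuse one patient's two single-modal predictions via branches A-C."""
    terms = fusion_terms(pred_a, pred_b)
    if terms.omega == 0:
        denom = pred_a.phi + pred_b.phi
        if denom > 0:
            eta = (pred_a.phi * pred_a.eta + pred_b.phi * pred_b.eta) / denom
        else:
            eta = 0.5 * (pred_a.eta + pred_b.eta)
        return FusedPrediction(rho=int(pred_a.rho), eta=float(eta), branch="agreement")
    branch: Branch = "accuracy" if terms.sigma != 0.0 else "confidence-tiebreak"
    return _resolve_disagreement(pred_a, pred_b, params, branch)


def fuse_batch(
    preds_a: SingleModalPrediction,
    preds_b: SingleModalPrediction,
    params: FusionParams = FusionParams(),
    eval_labels: np.ndarray | None = None,
) -> tuple[list[FusedPrediction], float | None]:
    """Elementwise CMF over two patient-aligned prediction sets.

    Each modality's set-level accuracy phi enters the rule for every
    patient. Returns the fused predictions and — when evaluation labels
    are supplied — the fused accuracy recomputed from the fused labels.
    """
    if preds_a.patient_ids != preds_b.patient_ids:
        raise ValueError("prediction sets are not patient-aligned")
    if preds_a.phi is None or preds_b.phi is None:
        raise ValueError("both prediction sets need accuracies phi for fusion")
    fused = [
        cmf_fuse(
            ModalPrediction(int(ra), float(ea), float(preds_a.phi)),
            ModalPrediction(int(rb), float(eb), float(preds_b.phi)),
            params,
        )
        for ra, ea, rb, eb in zip(preds_a.rho, preds_a.eta, preds_b.rho, preds_b.eta)
    ]
    accuracy = None
    if eval_labels is not None:
        y = np.asarray(eval_labels, dtype=int)
        if len(y) != len(fused):
            raise ValueError("eval_labels length does not match predictions")
        accuracy = float(np.mean(np.array([f.rho for f in fused]) == y))
    return fused, accuracy


# backwards-compatible private alias
_Single = ModalPrediction
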