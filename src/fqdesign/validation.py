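"""External (test-set) validation of a fitted QSAR model.

The external predictive determination coefficient is

    r2_pred = 1 - PRESS / SD

where PRESS is the sum of squared deviations between experimental and
predicted test-set values and SD is the sum of squared deviations of the
test-set experimental values from the mean experimental value of the
training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["ValidationReport", "r2_pred", "relative_error"]


@dataclass
class ValidationReport:
    press: float
    sd: float
    r2_pred: float
    per_compound: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_compound)

    def to_dict(self) -> dict:
        return asdict(self)


def relative_error(pred: float, ref: float) -> float:
    """Signed percent deviation of ``pred`` from the reference value."""
    if ref == 0:
        raise ValueError("relative error undefined for a zero reference")
    return (pred - ref) / ref * 100.0


def r2_pred(
    test_exp: np.ndarray,
    test_pred: np.ndarray,
    train_exp: np.ndarray,
    ids: list[str] | None = None,
) -> ValidationReport:
    """External predictive r^2 referenced to the training-set mean."""
    test_exp = np.asarray(test_exp, dtype=float).ravel()
    test_pred = np.asarray(test_pred, dtype=float).ravel()
    train_exp = np.asarray(train_exp, dtype=float).ravel()
    if test_exp.size == 0 or train_exp.size == 0:
        raise ValueError("test and training sets must be non-empty")
    if test_exp.size != test_pred.size:
        raise ValueError("experimental and predicted test values must pair up")
    press = float(np.sum((test_exp - test_pred) ** 2))
    sd = float(np.sum((test_exp - train_exp.mean()) ** 2))
    if sd == 0:
        raise ValueError(
            "degenerate test set: experimental values all equal the training mean"
        )
    rows = []
    ids = ids or [f"test-{i+1}" for i in range(test_exp.size)]
    for cid, e, p in zip(ids, test_exp, test_pred):
        rows.append(
            {
                "id": cid,
                "experimental": float(e),
                "predicted": float(p),
                "relative_error_pct": relative_error(float(p), float(e)),
            }
        )
    return ValidationReport(
        press=press, sd=sd, r2_pred=1.0 - press / sd, per_compound=rows
    )
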