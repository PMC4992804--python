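"""Per-subject elicited-P300 template (the Q vector of the correlation).

The template is the pointwise mean of normalized training epochs recorded
while the subject attended a known target, re-normalized to [0, 1].  Ten
source epochs is the reference configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, LengthError
from .preprocess import EPOCH_SAMPLES, Epoch, normalize01


@dataclass
class TemplateP300:
    """Averaged, normalized P300 reference for one subject."""

    samples: np.ndarray
    n_source_epochs: int = 10
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (EPOCH_SAMPLES,):
            raise LengthError(f"template must have {EPOCH_SAMPLES} samples")


def build_template(
    target_epochs: list[Epoch] | list[np.ndarray], subject_id: str = ""
) -> TemplateP300:
    """Average normalized target epochs into a template.

    Accepts Epoch objects (their normalized ``samples`` are used) or plain
    70-sample arrays, which are normalized first.  The mean is re-normalized
    to [0, 1]; if the mean is constant (e.g. epochs x and 1-x) the convention
    maps it to all 0.5.
    """
    if len(target_epochs) == 0:
        raise InvalidParameterError("build_template needs at least one epoch")
    rows = []
    for ep in target_epochs:
        x = ep.samples if isinstance(ep, Epoch) else np.asarray(ep, dtype=float)
        if x.shape != (EPOCH_SAMPLES,):
            raise LengthError(f"all epochs must have {EPOCH_SAMPLES} samples")
        rows.append(normalize01(x))
    mean = np.mean(rows, axis=0)
    return TemplateP300(
        samples=normalize01(mean),
        n_source_epochs=len(rows),
        subject_id=subject_id,
    )
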