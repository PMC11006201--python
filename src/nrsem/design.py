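"""Sample-size planning for structural equation models.

Rule-of-thumb planner: participants per free parameter (5-20), inflated by a
design effect for multistage sampling and by an expected non-response
fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass


@dataclass(frozen=True)
class DesignPlan:
    q: int
    ratio: float
    deff: float
    nonresponse: float
    n_base: int          # q * ratio
    n_design: int        # n_base * deff
    n_final: int         # ceil(n_design * (1 + nonresponse))


def plan_sample_size(q: int, ratio: float = 5.0, deff: float = 1.0,
                     nonresponse: float = 0.0) -> DesignPlan:
    """Staged sample size: ``q*ratio`` -> ``*deff`` -> ``*(1+f)`` (ceil).

    ``ratio`` outside the conventional [5, 20] band triggers a warning (the
    rule of thumb is breached) but not an error.
    """
    if q < 1:
        raise ValueError("free-parameter count q must be >= 1")
    if ratio < 1 or deff < 1:
        raise ValueError("ratio and design effect must be >= 1")
    if not (0 <= nonresponse < 1):
        raise ValueError("nonresponse fraction must be in [0, 1)")
    if not (5 <= ratio <= 20):
        warnings.warn(
            f"participants-per-parameter ratio {ratio} outside the conventional [5, 20] band",
            UserWarning, stacklevel=2,
        )
    n_base = math.ceil(q * ratio)
    n_design = math.ceil(n_base * deff)
    n_final = math.ceil(n_design * (1 + nonresponse))
    return DesignPlan(q=q, ratio=ratio, deff=deff, nonresponse=nonresponse,
                      n_base=n_base, n_design=n_design, n_final=n_final)
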