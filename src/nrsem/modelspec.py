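"""Plain-text model specification dialect.

One statement per line; ``#`` starts a comment.

* ``outcome ~ var + var + ...``      structural regression
* ``construct =~ item + item + ...`` measurement block
* ``outcome <- instruments: v, v``   instrument assignment for a loop variable
* ``psi: full|diag`` or ``psi: a~~b, c~~d``  disturbance covariance pattern

The same dialect feeds both the identification checks (regressions +
instruments) and the latent estimator (regressions + measurement blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .identify import StructuralSystem
from .sem import SemModel


@dataclass
class ParsedModel:
    measurement: dict[str, list[str]] = field(default_factory=dict)
    regressions: dict[str, list[str]] = field(default_factory=dict)
    instruments: dict[str, list[str]] = field(default_factory=dict)
    psi: str | list[tuple[str, str]] = "full"

    def sem_model(self) -> SemModel:
        return SemModel(measurement=dict(self.measurement),
                        regressions=dict(self.regressions), psi=self.psi)

    def structural_system(self, loop: tuple[str, ...] | None = None) -> StructuralSystem:
        endo = tuple(self.regressions)
        exo_seen: list[str] = []
        for preds in self.regressions.values():
            for p in preds:
                if p not in self.regressions and p not in exo_seen:
                    exo_seen.append(p)
        if loop is None:
            loop = tuple(v for v in endo
                         if any(v in self.regressions[w] and w in self.regressions[v]
                                for w in endo if w != v)) or endo
        return StructuralSystem(
            endogenous=endo, exogenous=tuple(exo_seen),
            equations={k: tuple(v) for k, v in self.regressions.items()},
            loop=loop,
            instruments={k: tuple(v) for k, v in self.instruments.items()},
        )


def parse_model(text: str) -> ParsedModel:
    model = ParsedModel()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("psi:"):
            body = line[4:].strip()
            if body in ("full", "diag"):
                model.psi = body
            else:
                pairs = []
                for chunk in body.split(","):
                    a, _, b = chunk.partition("~~")
                    if not b:
                        raise ValueError(f"line {lineno}: malformed psi pair {chunk!r}")
                    pairs.append((a.strip(), b.strip()))
                model.psi = pairs
        elif "<-" in line and "instruments:" in line:
            lhs, _, rhs = line.partition("<-")
            rhs = rhs.split("instruments:", 1)[1]
            model.instruments[lhs.strip()] = [v.strip() for v in rhs.split(",") if v.strip()]
        elif "=~" in line:
            lhs, _, rhs = line.partition("=~")
            model.measurement[lhs.strip()] = [v.strip() for v in rhs.split("+") if v.strip()]
        elif "~" in line:
            lhs, _, rhs = line.partition("~")
            model.regressions[lhs.strip()] = [v.strip() for v in rhs.split("+") if v.strip()]
        else:
            raise ValueError(f"line {lineno}: cannot parse {raw!r}")
    return model
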