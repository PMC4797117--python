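"""Run configuration shared by the builder, the pipeline and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

from .errors import ConfigurationError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All user-set parameters of a network construction run.

    alpha1 / alpha2 / alpha3 are the significance levels for the correlation,
    the partial correlation, and their difference; ``correction_alpha`` is the
    level applied to the multiplicity-corrected interference p-values.
    ``selection_mode`` picks how many regulators each layer keeps: ``topk``
    (requires ``k``), ``percent`` (requires ``percent``), or ``wscca``
    (``lam_grid``/``cv_folds``/``lam_scale`` apply).
    """

    alpha1: float = 0.05
    alpha2: float = 0.05
    alpha3: float = 0.05
    correction: str = "fdr_bh"
    correction_alpha: float = 0.05
    correction_mode: str = "operative"
    max_layers: int = 1
    selection_mode: str = "wscca"
    k: int | None = None
    percent: float | None = None
    lam_grid: Sequence[float] | None = None
    cv_folds: int = 5
    lam_scale: float = 1.0
    seed: int = 0
    output_prefix: str = "mlhgrn"

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "alpha3", "correction_alpha"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ConfigurationError(f"{name}={a!r} must lie in (0, 1)")
        if self.max_layers < 1:
            raise ConfigurationError(f"max_layers must be >= 1, got {self.max_layers}")
        if self.selection_mode not in ("topk", "percent", "wscca"):
            raise ConfigurationError(
                f"unknown selection_mode {self.selection_mode!r}"
            )
        if self.selection_mode == "topk":
            if self.k is None or self.k < 1:
                raise ConfigurationError("selection_mode 'topk' requires k >= 1")
        if self.selection_mode == "percent":
            if self.percent is None or not 0.0 < self.percent <= 100.0:
                raise ConfigurationError(
                    "selection_mode 'percent' requires percent in (0, 100]"
                )
        if self.selection_mode == "wscca" and self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["lam_grid"] is not None:
            d["lam_grid"] = list(d["lam_grid"])
        return d
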