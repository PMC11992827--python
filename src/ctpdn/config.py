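"""Run configuration shared across the pipeline stages.

All screening thresholds and model hyperparameters live here as defaults
rather than constants buried in the code, so the same pipeline can be run
against a different herbal formula or study design by editing one JSON file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any


@dataclass
class RunConfig:
    """Thresholds, hyperparameters and switches for a full pipeline run.

    Attributes
    ----------
    ob_min:
        Minimum oral bioavailability (percent) for a compound node.
    dl_min:
        Minimum drug-likeness score for a compound node.
    pathway_p_max:
        Strict upper bound on the enrichment p-value of a pathway node.
    tti_mode:
        ``"combined"`` treats the protein-protein combined score as the raw
        edge score S (reciprocal then taken by the length rule); ``"reciprocal"``
        uses S = 1/score instead.
    tpi_mode:
        ``"existence"`` scores target-pathway membership as S = 1;
        ``"qweight"`` uses S = -log10(q) clipped to [1e-3, 1e3].
    sigmoid_sign:
        Sign of the exponent in the logistic edge-weight map; +1 is the
        literal normalization rule, -1 is the mirrored variant.
    """

    # network node filters
    ob_min: float = 30.0
    dl_min: float = 0.18
    pathway_p_max: float = 1e-8

    # network edge construction
    tti_mode: str = "combined"
    tpi_mode: str = "existence"
    sigmoid_sign: int = 1

    # CTI classifier
    max_splits: int = 20
    n_learners: int = 30
    learning_rate: float = 0.1
    n_folds: int = 10
    normalization: str = "minmax"

    # metabolomics filter chain
    missing_max: float = 0.8
    rsd_max: float = 0.20
    sd_filter_fraction: float = 0.40
    vip_min: float = 1.0
    p_max: float = 0.05
    fc_min: float = 1.0
    autoscale: bool = False
    panel_size: int = 10

    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_max <= 1.0:
            raise ValueError("missing_max must be in [0, 1]")
        if not 0.0 <= self.sd_filter_fraction < 1.0:
            raise ValueError("sd_filter_fraction must be in [0, 1)")
        if self.rsd_max < 0 or self.pathway_p_max < 0 or self.pathway_p_max > 1:
            raise ValueError("threshold out of documented range")
        if self.tti_mode not in ("combined", "reciprocal"):
            raise ValueError(f"unknown tti_mode {self.tti_mode!r}")
        if self.tpi_mode not in ("existence", "qweight"):
            raise ValueError(f"unknown tpi_mode {self.tpi_mode!r}")
        if self.sigmoid_sign not in (1, -1):
            raise ValueError("sigmoid_sign must be +1 or -1")
        if self.normalization not in ("minmax", "zscore"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
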