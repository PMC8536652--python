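"""Study design: follow-up grid, covariate declarations and the L_D / L_Y partition.

The discrete follow-up grid has intervals ``0, 1, ..., K_plus_1`` where interval 0
is the randomization interval (carrying treatment assignment and baseline
covariates only) and ``K_plus_1`` is the last follow-up interval at which events
are recorded.  Event indicators C_k, D_k, Y_k exist for k = 1..K_plus_1 and
time-varying covariates L_k for k = 1..K_plus_1 - 1 (a covariate measured in the
final interval could never enter any hazard model).

The partition splits the time-varying covariates into a block L_D, assumed to
receive direct treatment effects only through the A_D component, and a block
L_Y, receiving them only through A_Y.  Within an interval the assumed temporal
order is (C_k, D_k, Y_k, L_{D,k}, L_{Y,k}).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class CovariatePartition:
    """Disjoint split of the time-varying covariate names into D- and Y-blocks."""

    L_D_names: tuple = ()
    L_Y_names: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "L_D_names", tuple(self.L_D_names))
        object.__setattr__(self, "L_Y_names", tuple(self.L_Y_names))
        overlap = set(self.L_D_names) & set(self.L_Y_names)
        if overlap:
            raise ConfigError(f"partition blocks overlap: {sorted(overlap)}")


@dataclass(frozen=True)
class StudyDesign:
    K_plus_1: int
    covariate_names: tuple = ()
    baseline_names: tuple = ()
    partition: CovariatePartition | None = None
    covariate_levels: dict = field(default_factory=dict)
    baseline_levels: dict = field(default_factory=dict)
    interval_labels: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        object.__setattr__(self, "baseline_names", tuple(self.baseline_names))
        if self.K_plus_1 < 1:
            raise ConfigError("K_plus_1 must be >= 1")
        if len(set(self.covariate_names)) != len(self.covariate_names):
            raise ConfigError("covariate names must be unique")
        if len(set(self.baseline_names)) != len(self.baseline_names):
            raise ConfigError("baseline names must be unique")
        if set(self.covariate_names) & set(self.baseline_names):
            raise ConfigError("covariate and baseline names must not overlap")
        part = self.partition
        if part is None:
            # default: everything in the D-block (the partition used by the
            # simplified nu2 estimator)
            part = CovariatePartition(L_D_names=self.covariate_names, L_Y_names=())
            object.__setattr__(self, "partition", part)
        declared = set(part.L_D_names) | set(part.L_Y_names)
        if declared != set(self.covariate_names):
            raise ConfigError(
                "partition must reference exactly the declared covariates; "
                f"got {sorted(declared)} vs {sorted(self.covariate_names)}"
            )
        if self.interval_labels is not None and len(self.interval_labels) != self.K_plus_1 + 1:
            raise ConfigError("interval_labels must have K_plus_1 + 1 entries")

    # -- derived quantities -------------------------------------------------

    @property
    def K(self) -> int:
        """Largest hazard index: risks nu_k are reported for k = 0..K."""
        return self.K_plus_1 - 1

    @property
    def n_cov_intervals(self) -> int:
        """Number of intervals at which time-varying covariates are measured."""
        return max(self.K_plus_1 - 1, 0)

    def levels_of(self, name: str) -> int:
        if name in self.covariate_names:
            return int(self.covariate_levels.get(name, 2))
        if name in self.baseline_names:
            return int(self.baseline_levels.get(name, 2))
        raise ConfigError(f"unknown covariate {name!r}")

    def with_partition(self, L_D_names, L_Y_names) -> "StudyDesign":
        return StudyDesign(
            K_plus_1=self.K_plus_1,
            covariate_names=self.covariate_names,
            baseline_names=self.baseline_names,
            partition=CovariatePartition(tuple(L_D_names), tuple(L_Y_names)),
            covariate_levels=dict(self.covariate_levels),
            baseline_levels=dict(self.baseline_levels),
            interval_labels=self.interval_labels,
        )

    # -- configuration file round-trip ---------------------------------------

    def to_dict(self) -> dict:
        return {
            "K_plus_1": self.K_plus_1,
            "covariates": list(self.covariate_names),
            "baseline": list(self.baseline_names),
            "partition": {
                "L_D": list(self.partition.L_D_names),
                "L_Y": list(self.partition.L_Y_names),
            },
            "covariate_levels": dict(self.covariate_levels),
            "baseline_levels": dict(self.baseline_levels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        try:
            part = d.get("partition") or {}
            return cls(
                K_plus_1=int(d["K_plus_1"]),
                covariate_names=tuple(d.get("covariates", ())),
                baseline_names=tuple(d.get("baseline", ())),
                partition=CovariatePartition(
                    tuple(part.get("L_D", ())), tuple(part.get("L_Y", ()))
                )
                if part
                else None,
                covariate_levels=dict(d.get("covariate_levels", {})),
                baseline_levels=dict(d.get("baseline_levels", {})),
            )
        except KeyError as exc:  # pragma: no cover - trivial
            raise ConfigError(f"design configuration missing key {exc}") from exc


def load_design(path) -> StudyDesign:
    """Read a StudyDesign from a YAML or JSON configuration file."""
    text = open(path, "r", encoding="utf-8").read()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"configuration file {path} does not contain a mapping")
    return StudyDesign.from_dict(data.get("design", data))


def dump_design(design: StudyDesign, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"design": design.to_dict()}, fh, sort_keys=False)
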