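"""Threshold decision tree staging myeloid cells from six features.

The tree maps a :class:`~cmlcells.morphometry.FeatureVector` to one of
eight outcomes: the six maturation stages Myeloblast (MB), Promyelocyte
(PM), Myelocyte (M), Metamyelocyte (MM), Band (B), Neutrophil (N), plus
the two deliberate overlap classes MB|PM and PM|M for borderline cells.
A ninth outcome, ``unclassifiable``, is produced when a feature required
by the branch actually taken is missing.

Stages, with every threshold overridable via :class:`ClassifierConfig`:

1.  more than one nucleus lobe -> N;
2.  T1/T2 > 0.92 -> regular-nucleus branch (stages 5-10);
3-4. 0.86 < T1/T2 <= 0.92 with ACoC < 30: the notch is ignored — T1 is
    rewritten to T2 (ratio 1) and the cell continues on the regular
    branch; with ACoC >= 30 the cell falls through to stage 11;
5.  T1/HD > 3.7 -> MB;
6-8. 2.1 < T1/HD <= 3.7: ACoC < 24 -> MB, ACoC > 27 -> PM, else MB|PM;
9-10. T1/HD <= 2.1: AoN < 110000 -> M, AoN > 115000 -> PM, else PM|M;
11. 0.53 <= T1/T2 <= 0.86 -> MM;
12. T1/T2 < 0.1 -> N;
13. 0.1 <= T1/T2 < 0.53: P1 > 475 -> B, else N.

Boundary convention: every comparison is strict as written, so a value
sitting exactly on a threshold falls to the non-strict side — e.g.
T1/T2 = 0.92 goes to the irregular branch, ACoC = 24 or 27 gives MB|PM,
AoN = 110000 or 115000 gives PM|M and P1 = 475 gives N.  The overlap
classes exist precisely to absorb such borderline cells.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import asdict, dataclass, replace
from enum import Enum
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = [
    "CmlClass",
    "UNCLASSIFIABLE",
    "ClassifierConfig",
    "ClassificationTrace",
    "classify",
    "classify_batch",
]


class CmlClass(str, Enum):
    """The eight maturation-stage outcomes."""

    MB = "MB"
    PM = "PM"
    M = "M"
    MM = "MM"
    B = "B"
    N = "N"
    MB_PM = "MB|PM"
    PM_M = "PM|M"


UNCLASSIFIABLE = "unclassifiable"

#: the full outcome set (8 labels + the missing-feature outcome)
OUTCOMES = tuple(c.value for c in CmlClass) + (UNCLASSIFIABLE,)


@dataclass
class ClassifierConfig:
    """All printed thresholds of the decision tree, overridable.

    Pixel-unit thresholds (``aon_*`` areas, ``p1_band`` length) are at the
    reference pitch; :meth:`scaled` rescales lengths linearly and areas
    quadratically for other pitches.
    """

    t1t2_regular: float = 0.92
    t1t2_notch_low: float = 0.86
    acoc_notch: float = 30.0
    t1hd_mb: float = 3.7
    t1hd_mid: float = 2.1
    acoc_mb: float = 24.0
    acoc_pm: float = 27.0
    aon_myelocyte: float = 110000.0
    aon_pm: float = 115000.0
    t1t2_mm_low: float = 0.53
    t1t2_neutrophil: float = 0.1
    p1_band: float = 475.0

    def __post_init__(self) -> None:
        if not (
            self.t1t2_neutrophil < self.t1t2_mm_low < self.t1t2_notch_low < self.t1t2_regular
        ):
            raise ValueError("T1/T2 thresholds must be strictly ordered")
        if not self.acoc_mb < self.acoc_pm:
            raise ValueError("acoc_mb must be below acoc_pm")
        if not self.aon_myelocyte <= self.aon_pm:
            raise ValueError("aon_myelocyte must not exceed aon_pm")
        if not self.t1hd_mid < self.t1hd_mb:
            raise ValueError("t1hd_mid must be below t1hd_mb")

    def scaled(self, factor: float) -> "ClassifierConfig":
        """Rescale pixel-unit thresholds for a pitch scaled by ``factor``
        (lengths x factor, areas x factor**2); ratios are unchanged."""
        return replace(
            self,
            aon_myelocyte=self.aon_myelocyte * factor**2,
            aon_pm=self.aon_pm * factor**2,
            p1_band=self.p1_band * factor,
        )

    # ---- (de)serialization --------------------------------------------

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = asdict(self)
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            path.write_text(yaml.safe_dump(data))
        else:
            path.write_text(json.dumps(data, indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "ClassifierConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ClassificationTrace:
    """Ordered list of visited stages and the final outcome, for audit."""

    stages: list[str]
    label: str


class _Missing(Exception):
    pass


def _req(value, name: str):
    if value is None:
        raise _Missing(name)
    return value


def classify(fv, cfg: ClassifierConfig | None = None) -> tuple[str, ClassificationTrace]:
    """Assign a maturation-stage label to one feature vector.

    Returns ``(label, trace)`` where ``label`` is one of the eight class
    strings or ``"unclassifiable"`` when a required feature is missing on
    the branch taken.
    """
    cfg = cfg or ClassifierConfig()
    stages: list[str] = []
    try:
        label = _classify(fv, cfg, stages)
    except _Missing as exc:
        logger.warning("cell unclassifiable: missing feature %s", exc)
        label = UNCLASSIFIABLE
    return label, ClassificationTrace(stages, label)


def _classify(fv, cfg: ClassifierConfig, stages: list[str]) -> str:
    stages.append("stage1:num")
    if _req(fv.num, "num") > 1:
        return CmlClass.N.value

    ratio = _req(fv.t1, "t1") / _req(fv.t2, "t2")
    t1 = fv.t1
    stages.append("stage2:t1/t2")
    regular = ratio > cfg.t1t2_regular
    if not regular and cfg.t1t2_notch_low < ratio <= cfg.t1t2_regular:
        stages.append("stage3:t1/t2-notch")
        stages.append("stage4:acoc")
        if _req(fv.acoc, "acoc") < cfg.acoc_notch:
            # ignore the notch: treat the nucleus as regular and use the
            # convex thickness in place of T1 downstream
            t1 = fv.t2
            ratio = 1.0
            regular = True
            stages.append("rewrite:t1:=t2")

    if regular:
        t1_hd = t1 / fv.hd if _req(fv.hd, "hd") > 0 else float("inf")
        stages.append("stage5:t1/hd")
        if t1_hd > cfg.t1hd_mb:
            return CmlClass.MB.value
        stages.append("stage6:t1/hd")
        if t1_hd > cfg.t1hd_mid:
            stages.append("stage7:acoc")
            if _req(fv.acoc, "acoc") < cfg.acoc_mb:
                return CmlClass.MB.value
            stages.append("stage8:acoc")
            if fv.acoc > cfg.acoc_pm:
                return CmlClass.PM.value
            return CmlClass.MB_PM.value
        stages.append("stage9:aon")
        if _req(fv.aon, "aon") < cfg.aon_myelocyte:
            return CmlClass.M.value
        stages.append("stage10:aon")
        if fv.aon > cfg.aon_pm:
            return CmlClass.PM.value
        return CmlClass.PM_M.value

    stages.append("stage11:t1/t2")
    # every cell on this branch already has ratio <= 0.92, and notch cells
    # with ACoC >= 30 (ratio in (0.86, 0.92]) are metamyelocytes too, so
    # only the lower bound is tested here
    if ratio >= cfg.t1t2_mm_low:
        return CmlClass.MM.value
    stages.append("stage12:t1/t2")
    if ratio < cfg.t1t2_neutrophil:
        return CmlClass.N.value
    stages.append("stage13:p1")
    if _req(fv.p1, "p1") > cfg.p1_band:
        return CmlClass.B.value
    return CmlClass.N.value


def classify_batch(
    fvs, cfg: ClassifierConfig | None = None
) -> list[str]:
    """Element-wise classification, order preserving; logs class counts."""
    cfg = cfg or ClassifierConfig()
    labels = [classify(fv, cfg)[0] for fv in fvs]
    counts = Counter(labels)
    logger.info("classified %d cells: %s", len(labels), dict(counts))
    return labels
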