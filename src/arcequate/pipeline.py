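"""End-to-end equating study orchestration.

The study design: a cohort of subjects with paired scores is split at
random into a conversion group A and a validation group B (stratified by
education so both halves match within every stratum).  Independently for
the total group and for each education stratum, anchors are extracted
from group A, the circle-arc model is fitted, the 0-30 conversion table
is built, scale consistency (MMSE vs MoCA) is measured in group A, and
the table is validated in group B by correlating converted against
observed target scores.  Group A/B baseline comparability is reported per
block.

Failures are isolated per analysis block — a stratum too small to place
three anchors is recorded with a machine-readable status and the run
continues — because small strata are expected in user data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .circle_arc import (AnchorTriplet, CircleArcModel, ConversionTable,
                         build_conversion_table, extract_anchors, fit_circle_arc)
from .consistency import (ConsistencyReport, GroupComparisonRow,
                          compare_groups, reports_to_frame,
                          scale_consistency, validate_conversion)
from .errors import ArcEquateError
from .score_data import (Cohort, EducationStrata, random_split, read_cohort,
                         stratify_by_education, write_cohort)
from .synthetic_data import GeneratorSpec, generate_cohort

BLOCKS = ("total", "low", "medium", "high")


@dataclass
class StudyConfig:
    """Inputs and knobs of one equating study run.

    Exactly one of ``cohort``, ``cohort_path`` or ``generator_spec`` must
    be set.  ``explicit_anchors`` maps block names (total/low/medium/high)
    to externally supplied anchor triplets; blocks without an entry use
    automatic anchor extraction from their group A.
    """

    cohort: Cohort | None = None
    cohort_path: str | Path | None = None
    generator_spec: GeneratorSpec | None = None
    boundaries: tuple[int, int] = (6, 9)
    split_seed: int = 0
    anchor_mode: str = "auto"  # "auto" | "explicit"
    explicit_anchors: Mapping[str, AnchorTriplet] = field(default_factory=dict)
    score_range: tuple[int, int] = (0, 30)
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        sources = [s is not None
                   for s in (self.cohort, self.cohort_path, self.generator_spec)]
        if sum(sources) != 1:
            raise ValueError(
                "exactly one of cohort, cohort_path, generator_spec must be set")
        if self.anchor_mode not in ("auto", "explicit"):
            raise ValueError(f"unknown anchor_mode {self.anchor_mode!r}")
        if self.anchor_mode == "explicit" and not self.explicit_anchors:
            raise ValueError("explicit anchor_mode needs explicit_anchors")

    def load_cohort(self) -> Cohort:
        if self.cohort is not None:
            return self.cohort
        if self.cohort_path is not None:
            return read_cohort(self.cohort_path)
        return generate_cohort(self.generator_spec)


@dataclass
class BlockResult:
    """One analysis block (total group or one education stratum)."""

    label: str
    status: str  # "ok" | "failed"
    n_a: int = 0
    n_b: int = 0
    anchors: AnchorTriplet | None = None
    model: CircleArcModel | None = None
    table: ConversionTable | None = None
    consistency_a: ConsistencyReport | None = None
    validation_b: ConsistencyReport | None = None
    comparison: list[GroupComparisonRow] = field(default_factory=list)
    error: str = ""


@dataclass
class StudyResult:
    """All artifacts of one study run, indexed by block name."""

    blocks: dict[str, BlockResult]
    group_a: Cohort
    group_b: Cohort
    config: StudyConfig

    def ok_blocks(self) -> list[str]:
        return [k for k, v in self.blocks.items() if v.status == "ok"]


def _run_block(label: str, group_a: Cohort, group_b: Cohort,
               config: StudyConfig) -> BlockResult:
    result = BlockResult(label=label, status="ok",
                         n_a=len(group_a), n_b=len(group_b))
    try:
        if label in config.explicit_anchors:
            result.anchors = extract_anchors(
                group_a, mode="explicit",
                explicit=config.explicit_anchors[label])
        elif config.anchor_mode == "explicit":
            raise ArcEquateError(
                f"explicit anchor mode but no anchors given for block {label!r}")
        else:
            result.anchors = extract_anchors(group_a, mode="auto")
        result.model = fit_circle_arc(result.anchors)
        lo, hi = config.score_range
        result.table = build_conversion_table(
            result.model, scores=range(lo, hi + 1), label=label)
        result.consistency_a = scale_consistency(group_a, label=f"{label}/A")
        result.validation_b = validate_conversion(
            group_b, result.table, label=f"{label}/B")
        result.comparison = compare_groups(group_a, group_b)
    except ArcEquateError as err:
        result.status = "failed"
        result.error = f"{type(err).__name__}: {err}"
    return result


def run_equating_study(config: StudyConfig) -> StudyResult:
    """Execute the full split/fit/convert/validate workflow.

    Reproducible from (config, split_seed); with explicit anchors the
    fitted models and tables do not depend on the split at all.
    """
    cohort = config.load_cohort()
    if len(cohort) == 0:
        raise ArcEquateError("cannot run a study on an empty cohort")
    strata = stratify_by_education(cohort, config.boundaries)
    group_a, group_b = random_split(cohort, config.split_seed, stratify_on=strata)
    strata_a = stratify_by_education(group_a, config.boundaries)
    strata_b = stratify_by_education(group_b, config.boundaries)

    blocks: dict[str, BlockResult] = {
        "total": _run_block("total", group_a, group_b, config)}
    for level in EducationStrata.LEVELS:
        blocks[level] = _run_block(
            level, strata_a.strata[level], strata_b.strata[level], config)

    result = StudyResult(blocks=blocks, group_a=group_a, group_b=group_b,
                         config=config)
    if config.output_dir is not None:
        write_study_outputs(result, config.output_dir)
    return result


def _sha256_of(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def anchors_frame(result: StudyResult) -> pd.DataFrame:
    rows = []
    for name, blk in result.blocks.items():
        if blk.anchors is None:
            continue
        a = blk.anchors
        rows.append({"block": name, "x1": a.x1, "y1": a.y1, "x2": a.x2,
                     "y2": a.y2, "x3": a.x3, "y3": a.y3})
    return pd.DataFrame(rows)


def model_params_frame(result: StudyResult) -> pd.DataFrame:
    rows = []
    for name, blk in result.blocks.items():
        if blk.model is None:
            continue
        m = blk.model
        rows.append({"block": name, "slope": m.slope, "intercept": m.intercept,
                     "y2_star": m.y2_star, "xc": m.xc, "yc": m.yc, "r": m.r,
                     "branch": m.branch, "status": blk.status})
    return pd.DataFrame(rows)


def write_study_outputs(result: StudyResult, output_dir: str | Path) -> None:
    """Write the tabular artifacts and an auditable run log."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_frame(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        written.append(path)

    _write_frame(anchors_frame(result), "anchors.csv")
    _write_frame(model_params_frame(result), "model_params.csv")

    for name, blk in result.blocks.items():
        if blk.table is not None:
            path = out / f"conversion_table_{name}.csv"
            blk.table.to_csv(path)
            written.append(path)

    reports = []
    for blk in result.blocks.values():
        if blk.consistency_a is not None:
            reports.append(blk.consistency_a)
        if blk.validation_b is not None:
            reports.append(blk.validation_b)
    _write_frame(reports_to_frame(reports), "consistency.csv")

    comparison_rows = []
    for name, blk in result.blocks.items():
        for row in blk.comparison:
            d = row.to_row()
            d["block"] = name
            comparison_rows.append(d)
    _write_frame(pd.DataFrame(comparison_rows), "group_comparison.csv")

    for grp, name in ((result.group_a, "group_A.csv"),
                      (result.group_b, "group_B.csv")):
        path = out / name
        write_cohort(grp, path)
        written.append(path)

    log = {
        "package_version": __version__,
        "split_seed": result.config.split_seed,
        "boundaries": list(result.config.boundaries),
        "anchor_mode": result.config.anchor_mode,
        "score_range": list(result.config.score_range),
        "block_status": {k: v.status for k, v in result.blocks.items()},
        "block_errors": {k: v.error for k, v in result.blocks.items() if v.error},
        "n": {"A": len(result.group_a), "B": len(result.group_b)},
        "artifact_sha256": {p.name: _sha256_of(p) for p in written},
    }
    (out / "run_log.txt").write_text(
        json.dumps(log, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _parse_anchor_string(text: str) -> AnchorTriplet:
    """Parse ``x1,y1;x2,y2;x3,y3`` into an anchor triplet."""
    points = []
    for chunk in text.split(";"):
        xs = chunk.strip().lstrip("(").rstrip(")").split(",")
        if len(xs) != 2:
            raise ValueError(f"bad anchor point {chunk!r}; want 'x,y;x,y;x,y'")
        points.append((float(xs[0]), float(xs[1])))
    if len(points) != 3:
        raise ValueError(f"need exactly 3 anchor points, got {len(points)}")
    (x1, y1), (x2, y2), (x3, y3) = points
    return AnchorTriplet(x1=x1, y1=y1, x2=x2, y2=y2, x3=x3, y3=y3)


def read_study_config(path: str | Path) -> StudyConfig:
    """Parse a StudyConfig from an INI-style ``key = value`` file.

    ``[study]`` holds cohort path / boundaries / split_seed / anchor_mode /
    score_range / output_dir; ``[anchors]`` optionally maps block names to
    ``x1,y1;x2,y2;x3,y3`` triplets; a ``[generator]`` section (plus
    optional ``[strata]``/``[low]``/``[medium]``/``[high]``) delegates to
    the synthetic-cohort generator instead of a cohort file.
    """
    import configparser

    from .synthetic_data import read_generator_spec

    parser = configparser.ConfigParser()
    if not parser.read(path):
        raise FileNotFoundError(path)
    kwargs: dict = {}
    study = parser["study"] if parser.has_section("study") else {}
    if "cohort" in study:
        kwargs["cohort_path"] = Path(path).parent / study["cohort"]
    elif parser.has_section("generator"):
        kwargs["generator_spec"] = read_generator_spec(path)
    if "boundaries" in study:
        lo, hi = (int(v) for v in study["boundaries"].split(","))
        kwargs["boundaries"] = (lo, hi)
    if "split_seed" in study:
        kwargs["split_seed"] = int(study["split_seed"])
    if "anchor_mode" in study:
        kwargs["anchor_mode"] = study["anchor_mode"].strip()
    if "score_range" in study:
        lo, hi = (int(v) for v in study["score_range"].split(","))
        kwargs["score_range"] = (lo, hi)
    if "output_dir" in study:
        kwargs["output_dir"] = Path(path).parent / study["output_dir"]
    if parser.has_section("anchors"):
        kwargs["explicit_anchors"] = {
            block: _parse_anchor_string(text)
            for block, text in parser["anchors"].items()}
    return StudyConfig(**kwargs)
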