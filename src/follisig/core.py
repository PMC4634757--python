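"""Shared vocabulary and validation for the follicle-staging pipeline.

Samples are laser-capture-microdissected follicular compartments — the
oocyte (``O``) and its surrounding granulosa cells (``GC``) — taken at the
four earliest follicular stages: primordial (``PD``), primary (``PM``),
secondary (``SC``) and small antral (``SA``).  Multi-tissue RNA pools
(``MT``) carry no stage and serve as a specificity background.
"""

from __future__ import annotations

import pandas as pd

STAGES: tuple[str, ...] = ("PD", "PM", "SC", "SA")
COMPARTMENTS: tuple[str, ...] = ("O", "GC")
MT = "MT"
NO_STAGE = "NONE"

#: design-sheet column contract used by every table reader/writer
DESIGN_COLUMNS = ("sample_id", "compartment", "stage", "replicate")


class InvalidArgument(ValueError):
    """A precondition on user input was violated."""


class QualityFailure(RuntimeError):
    """A fitted quantity failed a sanity check (e.g. non-amplifying assay)."""


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check a sample design sheet and return it with canonical dtypes.

    Required columns: ``sample_id, compartment, stage, replicate``.  A row
    has ``stage == "NONE"`` exactly when ``compartment == "MT"``; sample ids
    must be unique.
    """
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise InvalidArgument(f"design sheet is missing columns: {sorted(missing)}")
    out = design.loc[:, list(DESIGN_COLUMNS)].copy()
    out["sample_id"] = out["sample_id"].astype(str)
    if out["sample_id"].duplicated().any():
        dup = out.loc[out["sample_id"].duplicated(), "sample_id"].tolist()
        raise InvalidArgument(f"duplicate sample ids: {dup}")
    bad_comp = ~out["compartment"].isin((*COMPARTMENTS, MT))
    if bad_comp.any():
        raise InvalidArgument(
            f"unknown compartments: {sorted(out.loc[bad_comp, 'compartment'].unique())}"
        )
    bad_stage = ~out["stage"].isin((*STAGES, NO_STAGE))
    if bad_stage.any():
        raise InvalidArgument(
            f"unknown stages: {sorted(out.loc[bad_stage, 'stage'].unique())}"
        )
    mt = out["compartment"] == MT
    if (mt & (out["stage"] != NO_STAGE)).any() or (~mt & (out["stage"] == NO_STAGE)).any():
        raise InvalidArgument("stage must be NONE iff compartment is MT")
    out["replicate"] = out["replicate"].astype(int)
    if (out["replicate"] < 1).any():
        raise InvalidArgument("replicate indices must be positive")
    return out.reset_index(drop=True)


def group_label(stage: str, compartment: str) -> str:
    """Study-style group name, e.g. ``PDO`` for primordial oocytes, ``PMG``
    for primary granulosa, or ``MT`` for the multi-tissue pools."""
    if compartment == MT:
        return MT
    return f"{stage}{'O' if compartment == 'O' else 'G'}"


def lcm_groups() -> list[tuple[str, str]]:
    """The 8 stage x compartment groups, oocytes first, in stage order."""
    return [(s, c) for c in COMPARTMENTS for s in STAGES]
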