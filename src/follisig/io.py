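"""TSV and YAML round-trip helpers with fixed column contracts.

Wide tables (counts, relative expression, detection) are gene x sample
with the first column ``gene``; missing wells are written as ``NA``.
Ct tables use a long format (gene, sample_id, ct).  Model fits serialize
to YAML with full float precision so a reloaded fit reproduces its
predictions bit for bit.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import validate_design
from .hurdle import HurdleFit, PartFit

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_counts",
    "read_counts",
    "write_design",
    "read_design",
    "write_ct_long",
    "read_ct_long",
    "write_observation_vector",
    "read_observation_vector",
    "save_hurdle_fit",
    "load_hurdle_fit",
]


def write_matrix(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene", na_values=["NA"])


def write_counts(counts: pd.DataFrame, path) -> None:
    out = counts.astype(int)
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene").astype(int)


def write_design(design: pd.DataFrame, path) -> None:
    validate_design(design).to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    return validate_design(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def write_ct_long(ct: pd.DataFrame, path) -> None:
    long = ct.stack(future_stack=True).rename("ct").reset_index()
    long.columns = ["gene", "sample_id", "ct"]
    long.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


def read_ct_long(path) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"sample_id": str})
    missing = {"gene", "sample_id", "ct"} - set(long.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return long.pivot(index="gene", columns="sample_id", values="ct")


def write_observation_vector(obs, path) -> None:
    """Write one prediction input as TSV (gene, z, y; y is NA where z=0)."""
    df = pd.DataFrame({"gene": obs.z.index, "z": obs.z.to_numpy(), "y": obs.y.to_numpy()})
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


def read_observation_vector(path, compartment: str):
    from .predict import ObservationVector

    df = pd.read_csv(path, sep="\t", na_values=["NA"]).set_index("gene")
    return ObservationVector(
        compartment=compartment, z=df["z"].astype(int), y=df["y"].astype(float)
    )


# ---------------------------------------------------------------------------
# fit serialization
# ---------------------------------------------------------------------------

def _part_to_dict(part: PartFit) -> dict:
    return {
        "part": part.part,
        "structure": part.structure,
        "beta": {k: float(v) for k, v in part.beta.items()},
        "beta_se": {k: float(v) for k, v in part.beta_se.items()},
        "cov": {
            "labels": list(part.cov.index),
            "values": [[float(x) for x in row] for row in part.cov.to_numpy()],
        },
        "modes": {
            "genes": list(part.modes.index),
            "labels": list(part.modes.columns),
            "values": [[float(x) for x in row] for row in part.modes.to_numpy()],
        },
        "mode_cov": [[[float(x) for x in row] for row in m] for m in part.mode_cov],
        "loglik": float(part.loglik),
        "resid_sd": None if part.resid_sd is None else float(part.resid_sd),
        "converged": bool(part.converged),
        "n_iter": int(part.n_iter),
        "separation": bool(part.separation),
        "ridge_used": float(part.ridge_used),
        "loglik_trace": [float(x) for x in part.loglik_trace],
    }


def _part_from_dict(d: dict) -> PartFit:
    labels = d["cov"]["labels"]
    return PartFit(
        part=d["part"],
        structure=d["structure"],
        beta=pd.Series(d["beta"]),
        beta_se=pd.Series(d["beta_se"]),
        cov=pd.DataFrame(np.array(d["cov"]["values"], dtype=float).reshape(len(labels), len(labels)), index=labels, columns=labels),
        modes=pd.DataFrame(
            np.array(d["modes"]["values"], dtype=float).reshape(
                len(d["modes"]["genes"]), len(d["modes"]["labels"])
            ),
            index=d["modes"]["genes"],
            columns=d["modes"]["labels"],
        ),
        mode_cov=np.array(d["mode_cov"], dtype=float),
        loglik=d["loglik"],
        resid_sd=d["resid_sd"],
        converged=d["converged"],
        n_iter=d["n_iter"],
        separation=d["separation"],
        ridge_used=d["ridge_used"],
        loglik_trace=d["loglik_trace"],
    )


def save_hurdle_fit(fit: HurdleFit, path) -> None:
    doc = {
        "format": "follisig-hurdle-fit/1",
        "genes": list(fit.genes),
        "presence": _part_to_dict(fit.presence),
        "level": _part_to_dict(fit.level),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_hurdle_fit(path) -> HurdleFit:
    doc = yaml.safe_load(Path(path).read_text())
    if doc.get("format") != "follisig-hurdle-fit/1":
        raise ValueError("not a follisig hurdle-fit file")
    return HurdleFit(
        presence=_part_from_dict(doc["presence"]),
        level=_part_from_dict(doc["level"]),
        genes=doc["genes"],
    )
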