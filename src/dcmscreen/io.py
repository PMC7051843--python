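"""File formats, configuration and artifact metadata for the pipeline.

CSV conventions: comma-separated UTF-8 with a header row, ``NA`` (or empty)
for missing responses.  Every artifact the pipeline writes embeds the
configuration hash and seed — TSV/CSV files as a leading ``#`` comment
line, JSON files in a ``meta`` object — so a report stage can refuse to
aggregate artifacts produced under different configurations.

Probabilities are serialized at full double precision in JSON; TSV output
is rounded to 3 decimals for display only.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gdina import CalibrationResult, FitOptions, ItemParams
from .profiles import QMatrix

__all__ = [
    "read_responses_csv",
    "write_responses_csv",
    "config_hash",
    "load_config",
    "default_config",
    "write_table",
    "read_table_meta",
    "calibration_to_json",
    "calibration_params_from_json",
]


def read_responses_csv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a respondents x items 0/1/NA matrix.

    Returns (X, respondent_ids, item_ids); X is float with NaN for missing.
    Malformed cells are reported with their row and column labels.
    """
    df = pd.read_csv(path, index_col=0, comment="#", na_values=["NA"])
    X = df.to_numpy(dtype=float)
    bad = ~(np.isnan(X) | np.isin(X, (0.0, 1.0)))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"non-binary cell at respondent {df.index[i]!r}, "
            f"item {df.columns[j]!r}: {df.iat[i, j]!r}"
        )
    return X, [str(i) for i in df.index], [str(c) for c in df.columns]


def write_responses_csv(path: str | Path, X: np.ndarray, item_ids,
                        respondent_ids=None, meta: dict | None = None) -> None:
    ids = respondent_ids or [str(i + 1) for i in range(X.shape[0])]
    df = pd.DataFrame(X, index=ids, columns=list(item_ids))
    df.index.name = "respondent"
    # store as integers where observed
    with open(path, "w") as fh:
        if meta:
            fh.write(_meta_comment(meta))
        df.to_csv(fh, na_rep="NA",
                  float_format=lambda v: f"{int(v)}" if v == v else "NA")


def config_hash(config: dict) -> str:
    """Short stable hash of a config mapping (canonical JSON, sha256)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def default_config() -> dict:
    return {
        "seed": 0,
        "estimation": {
            "max_iter": 1000,
            "tol": 1.0e-4,
            "loglik_tol": 1.0e-6,
            "monotone": True,
            "struct": "saturated",
        },
        "thresholds": {"disc_min": 0.30, "fit_alpha": 0.01, "dif_alpha": 0.01},
        "screening": {"cut": 0.5, "min_symptoms": 5, "method": "marginal"},
        "simulate": {
            "n_respondents": 980,
            "n_items": 74,
            "n_symptoms": 9,
            "flip_prob": 0.1,
            "highrisk_min": 6,
        },
    }


def load_config(path: str | Path | None) -> dict:
    """Defaults overlaid with a YAML config file; unknown keys rejected."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for section, value in user.items():
        if section not in cfg:
            raise ValueError(f"unknown config section {section!r}")
        if isinstance(cfg[section], dict):
            unknown = set(value) - set(cfg[section])
            if unknown:
                raise ValueError(
                    f"unknown config keys in {section!r}: {sorted(unknown)}"
                )
            cfg[section].update(value)
        else:
            cfg[section] = value
    return cfg


def fit_options_from_config(cfg: dict) -> FitOptions:
    est = cfg["estimation"]
    return FitOptions(
        max_iter=int(est["max_iter"]),
        tol=float(est["tol"]),
        loglik_tol=float(est["loglik_tol"]),
        monotone=bool(est["monotone"]),
        struct=str(est["struct"]),
    )


def _meta_comment(meta: dict) -> str:
    kv = " ".join(f"{k}={v}" for k, v in meta.items())
    return f"# dcmscreen {kv}\n"


def write_table(path: str | Path, df: pd.DataFrame, meta: dict,
                sep: str = "\t") -> None:
    """TSV artifact with the metadata comment line; floats shown to 3 dp."""
    with open(path, "w") as fh:
        fh.write(_meta_comment(meta))
        df.to_csv(fh, sep=sep, index=False, float_format="%.3f")


def read_table_meta(path: str | Path) -> dict:
    """Parse the leading metadata comment of an artifact (empty if absent)."""
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("# dcmscreen"):
        return {}
    return dict(
        kv.split("=", 1) for kv in first.removeprefix("# dcmscreen").split()
    )


def calibration_to_json(result: CalibrationResult, meta: dict) -> dict:
    """JSON-serializable calibration artifact (posterior omitted for size)."""
    return {
        "meta": meta,
        "loglik": result.loglik,
        "n_iter": result.n_iter,
        "converged": bool(result.converged),
        "class_dist": result.class_dist.tolist(),
        "symptom_ids": list(result.qmatrix.symptom_ids),
        "items": [
            {
                "item": ip.item_id,
                "deltas": ip.deltas.tolist(),
                "probs": ip.probs.tolist(),
                "discrimination": ip.discrimination,
            }
            for ip in result.item_params
        ],
        "eap": result.eap.tolist(),
    }


def calibration_params_from_json(doc: dict) -> tuple[list[ItemParams], np.ndarray]:
    """Item parameters and class distribution back from the JSON artifact."""
    items = [
        ItemParams(rec["item"], np.asarray(rec["deltas"], dtype=float))
        for rec in doc["items"]
    ]
    return items, np.asarray(doc["class_dist"], dtype=float)
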