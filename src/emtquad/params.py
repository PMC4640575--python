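"""Parameter file loading, validation and the packaged default set.

Parameter files are flat JSON: symbol -> value, with the four
occupancy-coefficient vectors stored as JSON arrays.  The packaged
default set is a reconstructed basal parameterisation produced by the
calibration search in :mod:`emtquad.calibrate`; it satisfies the
structural constraints of the four-state circuit (tetra-stable TGF-β
window, monostable M at high TGF-β, Ovol2-driven reprogramming to E)
and is labelled "reconstructed" in run logs.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import logging
from pathlib import Path

from .model import ParameterError, ParameterSet

log = logging.getLogger("emtquad")

DEFAULT_PARAMS_RESOURCE = "default_params.json"


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def load_params(path) -> ParameterSet:
    """Load and validate a flat-JSON parameter file.

    Missing and unexpected symbols are enumerated in a single
    :class:`~emtquad.model.ParameterError`.  The file's SHA-256 digest
    is logged for provenance.
    """
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"parameter file not found: {path}")
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParameterError(f"parameter file {path} is not valid JSON: {exc}") from exc
    params = ParameterSet.from_dict(data)
    log.info("loaded parameters from %s (sha256=%s)", path, file_sha256(path))
    return params


def save_params(params: ParameterSet, path) -> None:
    params.to_json(path)


def default_params() -> ParameterSet:
    """The packaged reconstructed basal parameter set."""
    ref = importlib.resources.files("emtquad.params_data").joinpath(
        DEFAULT_PARAMS_RESOURCE
    )
    params = ParameterSet.from_dict(json.loads(ref.read_text()))
    log.info("loaded packaged default (reconstructed) basal parameter set")
    return params
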