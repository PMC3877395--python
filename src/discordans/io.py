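"""HDF5 record I/O.

Every output file is self-describing: the record arrays plus the resolved
configuration (JSON attribute), the seed and the package version, so that
(config, seed) regenerate the file exactly.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from . import __version__
from .analytics import AlternansRecord

__all__ = ["write_record", "read_record", "CorruptRecordError"]

_SENTINEL = "discordans-record-complete"


class CorruptRecordError(RuntimeError):
    """The file is not a complete record written by this package."""


def write_record(record: AlternansRecord, path, config: dict | None = None,
                 extras: dict | None = None) -> None:
    """Write a record to HDF5 (lossless round trip of all arrays).

    ``extras`` may hold additional named float arrays (e.g. activation maps).
    The completeness sentinel is written last, so a partially written file is
    detected on read.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("c", data=record.c)
        f.create_dataset("a", data=record.a)
        f.create_dataset("cl", data=record.cl)
        if record.capture is not None:
            f.create_dataset("capture", data=record.capture.astype(np.uint8))
        for k, v in (extras or {}).items():
            f.create_dataset(f"extras/{k}", data=np.asarray(v))
        f.attrs["seed"] = -1 if record.seed is None else int(record.seed)
        f.attrs["meta"] = json.dumps(record.meta)
        f.attrs["config"] = json.dumps(config or {})
        f.attrs["version"] = __version__
        f.attrs["complete"] = _SENTINEL


def read_record(path):
    """Read a record written by :func:`write_record`.

    Returns (AlternansRecord, config dict, extras dict).  Raises
    :class:`CorruptRecordError` for partial or foreign files.
    """
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("complete") != _SENTINEL:
                raise CorruptRecordError(f"{path}: incomplete or foreign file")
            c = f["c"][...]
            a = f["a"][...]
            cl = f["cl"][...]
            capture = f["capture"][...].astype(bool) if "capture" in f else None
            seed = int(f.attrs["seed"])
            meta = json.loads(f.attrs["meta"])
            config = json.loads(f.attrs["config"])
            extras = {}
            if "extras" in f:
                for k in f["extras"]:
                    extras[k] = f["extras"][k][...]
    except (OSError, KeyError) as e:
        raise CorruptRecordError(f"{path}: {e}") from e
    rec = AlternansRecord(c=c, a=a, cl=cl, capture=capture,
                          seed=None if seed == -1 else seed, meta=meta)
    return rec, config, extras
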