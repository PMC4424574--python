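"""Small shared helpers: chromosome ordering, rounding, atomic writes."""

from __future__ import annotations

import math
import os
import re
import tempfile
from contextlib import contextmanager

_CHROM_RE = re.compile(r"^(chr)?(\w+)$", re.IGNORECASE)


def chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    """Natural chromosome order: chr1 < chr2 < ... < chr22 < chrX < chrY < chrM."""
    m = _CHROM_RE.match(chrom.strip())
    body = m.group(2) if m else chrom
    if body.isdigit():
        return (0, int(body))
    special = {"X": 100, "Y": 101, "M": 102, "MT": 102}
    if body.upper() in special:
        return (0, special[body.upper()])
    return (1, body)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (so 0.45 -> 0.5 at 1 decimal), unlike banker's rounding."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@contextmanager
def atomic_write(path: str | os.PathLike, mode: str = "w"):
    """Write to a temp file in the target directory, then rename into place."""
    path = os.fspath(path)
    directory = os.path.dirname(os.path.abspath(path))
    os.makedirs(directory, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".tmp-", suffix=os.path.basename(path))
    try:
        with os.fdopen(fd, mode) as handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise
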