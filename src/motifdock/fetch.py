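"""Optional helper for fetching PDB entries into a local cache.

Core functionality never requires downloads: synthetic fixtures cover every
code path. This helper exists for regression analyses against published
structures. Files are cached under ``$MOTIFDOCK_PDB_CACHE`` (default
``~/.cache/motifdock/pdb``) and reused on later calls.
"""

from __future__ import annotations

import os
import urllib.error
import urllib.request
from pathlib import Path

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


class FetchUnavailableError(Exception):
    """Raised when an entry is neither cached nor downloadable."""


def cache_dir() -> Path:
    env = os.environ.get("MOTIFDOCK_PDB_CACHE")
    return Path(env) if env else Path.home() / ".cache" / "motifdock" / "pdb"


def fetch_pdb(pdb_id: str, cache: Path | None = None, timeout: float = 30.0) -> Path:
    """Return a local path to the PDB entry, downloading it if needed."""
    pdb_id = pdb_id.upper()
    if len(pdb_id) != 4 or not pdb_id.isalnum():
        raise ValueError(f"not a PDB id: {pdb_id!r}")
    cache = cache or cache_dir()
    path = cache / f"{pdb_id}.pdb"
    if path.exists():
        return path
    cache.mkdir(parents=True, exist_ok=True)
    url = RCSB_URL.format(pdb_id=pdb_id)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as response:
            data = response.read()
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise FetchUnavailableError(
            f"PDB entry {pdb_id} is not in the cache ({path}) and could not "
            f"be downloaded from {url}: {exc}. Place the file in the cache "
            "directory to run structure regressions offline.") from exc
    path.write_bytes(data)
    return path
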