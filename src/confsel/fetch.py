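"""Optional download helpers for public accessions (PDB, BMRB).

Kept separate from the analysis modules: nothing in the package or the test
suite imports this module, so the pipeline stays fully offline-capable. Use
these only to populate a local data directory when network access exists.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

PDB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"
BMRB_URL = "https://bmrb.io/ftp/pub/bmrb/entry_directories/bmr{entry}/bmr{entry}_3.str"


def fetch_pdb(pdb_id: str, dest_dir: str | Path) -> Path:
    """Download a PDB coordinate file (text format) to ``dest_dir``."""
    dest = Path(dest_dir) / f"{pdb_id.upper()}.pdb"
    urllib.request.urlretrieve(PDB_URL.format(pdb_id=pdb_id.upper()), dest)
    return dest


def fetch_bmrb(entry: int | str, dest_dir: str | Path) -> Path:
    """Download an NMR-STAR v3 entry file from the BMRB to ``dest_dir``."""
    dest = Path(dest_dir) / f"bmr{entry}.str"
    urllib.request.urlretrieve(BMRB_URL.format(entry=entry), dest)
    return dest
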