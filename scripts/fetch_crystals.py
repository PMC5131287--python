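#!/usr/bin/env python
"""Download the three study crystal structures into data/crystals/.

Requires network access to the RCSB PDB.  The crystal-count tests in
tests/test_acceptance.py read the files from data/crystals/<code>.pdb.
"""

import urllib.request
from pathlib import Path

CODES = ("1BRS", "3U43", "4KE2")
DEST = Path(__file__).resolve().parent.parent / "data" / "crystals"


def main() -> int:
    DEST.mkdir(parents=True, exist_ok=True)
    for code in CODES:
        out = DEST / f"{code.lower()}.pdb"
        if out.exists():
            print(f"{out} already present")
            continue
        url = f"https://files.rcsb.org/download/{code}.pdb"
        print(f"fetching {url} -> {out}")
        urllib.request.urlretrieve(url, out)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
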