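"""Optional helper: fetch the deposited honeybee mitogenome records.

Downloads the GenBank flat files used by the real-data checks into
``data/real/`` (the library itself never requires network access):

    MW811175    A. m. carnica, Slovenia  (SICarnica)
    MN250878    A. m. carnica, Austria   (ATCarnica)
    NC_001566   A. m. ligustica          (REFLigustica)
    GQ162109    A. cerana outgroup       (optional)

Usage:  python scripts/fetch_accessions.py [--outdir data/real]
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

ACCESSIONS = ["MW811175", "MN250878", "NC_001566", "GQ162109"]
EUTILS = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&rettype=gb&retmode=text&id={acc}"
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path,
                    default=Path(__file__).resolve().parent.parent / "data" / "real")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        dest = args.outdir / f"{acc}.gb"
        if dest.exists():
            print(f"{dest} already present")
            continue
        url = EUTILS.format(acc=acc)
        print(f"fetching {acc} ...")
        try:
            with urllib.request.urlopen(url, timeout=60) as resp:
                data = resp.read()
        except OSError as exc:
            print(f"  failed: {exc}", file=sys.stderr)
            continue
        if not data.startswith(b"LOCUS"):
            print(f"  unexpected payload for {acc}; skipped", file=sys.stderr)
            continue
        dest.write_bytes(data)
        print(f"  wrote {dest} ({len(data)} bytes)")


if __name__ == "__main__":
    main()
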