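#!/usr/bin/env python
"""Fetch the two divergent beta-like large-subunit sequences from NCBI.

Downloads XP_639969.1 (Dictyostelium discoideum TPLATE/beta-like subunit)
and NP_186827.2 (Arabidopsis thaliana TPLATE) and stores them at
``data/reference_pair.faa`` so the divergent-pair identity check can run.
Requires network access; the library itself never fetches anything.

Usage:
    python scripts/fetch_reference_pair.py
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

ACCESSIONS = "XP_639969.1,NP_186827.2"
URL = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    f"?db=protein&id={ACCESSIONS}&rettype=fasta&retmode=text"
)
OUT = Path(__file__).resolve().parent.parent / "data" / "reference_pair.faa"


def main() -> int:
    try:
        with urllib.request.urlopen(URL, timeout=60) as resp:
            text = resp.read().decode()
    except OSError as exc:
        print(f"fetch failed ({exc}); network access is required", file=sys.stderr)
        return 1
    if not text.startswith(">"):
        print("unexpected response; no FASTA returned", file=sys.stderr)
        return 1
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(text)
    print(f"wrote {OUT}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
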