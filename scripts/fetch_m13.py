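#!/usr/bin/env python
"""Download the 520 bp M13 bacteriophage fragment used in the published
worked example (GenBank NC_003287.2, positions 521-1041) into
tests/data/m13_nc003287_521_1041.fasta.

This is an optional asset: nothing in the package or test suite requires
it, and it is never fetched at build or test time.  Run it once, with
network access, to reproduce the worked example on the real sequence:

    python scripts/fetch_m13.py
    oligotiler design --input tests/data/m13_nc003287_521_1041.fasta \
        --out-prefix m13 --target-tm 56
"""

from pathlib import Path
from urllib.request import urlopen

URL = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id=NC_003287.2&rettype=fasta&retmode=text"
    "&seq_start=521&seq_stop=1041"
)
DEST = Path(__file__).resolve().parent.parent / "tests" / "data"


def main() -> None:
    DEST.mkdir(parents=True, exist_ok=True)
    out = DEST / "m13_nc003287_521_1041.fasta"
    with urlopen(URL, timeout=60) as response:
        data = response.read()
    if not data.startswith(b">"):
        raise SystemExit("unexpected response from NCBI efetch")
    out.write_bytes(data)
    print(f"wrote {out} ({len(data)} bytes)")


if __name__ == "__main__":
    main()
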