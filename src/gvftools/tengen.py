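"""The 10Gen reference-dataset metadata table.

The 10Gen dataset is a public collection of ten personal-genome variant
files distributed as GVF for benchmarking personal-genomics software;
one individual (NA18507) appears twice, sequenced on two platforms.  The toolkit bundles the catalogue —
filename, individual, ethnicity, sequencing platform — for documentation
and as a template library for ``##technology-platform`` provenance
pragmas.  The genome files themselves are external downloads and are not
shipped.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = ("filename", "individual", "ethnicity", "platform")

_ROWS = (
    ("10Gen_NA19240_SNV", "NA19240", "African", "Life SOLiD"),
    ("10Gen_NA18507_ILMN_SNV", "NA18507", "African", "Illumina"),
    ("10Gen_NA18507_SOLiD_SNV", "NA18507", "African", "Life SOLiD"),
    ("10Gen_Chinese_SNV", "Chinese", "Asian", "Illumina"),
    ("10Gen_Korean_SNV", "Korean", "Asian", "Illumina"),
    ("10Gen_Venter_SNV", "Venter", "Caucasian", "Sanger"),
    ("10Gen_Watson_SNV", "Watson", "Caucasian", "Roche 454"),
    ("10Gen_NA07022_SNV", "NA07022", "Caucasian", "CGenomics"),
    ("10Gen_NA12878_SNV", "NA12878", "Caucasian", "ABI SOLiD"),
    ("10Gen_Quake_SNV", "Quake", "Caucasian", "Helicos"),
)


def tengen_metadata() -> pd.DataFrame:
    """The 10Gen catalogue as a DataFrame (one row per distributed file)."""
    return pd.DataFrame(list(_ROWS), columns=list(_COLUMNS))


def tengen_lookup(individual: str | None = None, platform: str | None = None) -> pd.DataFrame:
    """Filter the catalogue; unknown values yield an empty frame."""
    df = tengen_metadata()
    if individual is not None:
        df = df[df["individual"] == individual]
    if platform is not None:
        df = df[df["platform"] == platform]
    return df.reset_index(drop=True)


def technology_platform_pragma(filename: str) -> dict[str, str]:
    """A ``##technology-platform`` tag map templated from a catalogue row."""
    df = tengen_metadata()
    row = df[df["filename"] == filename]
    if row.empty:
        raise KeyError(f"unknown 10Gen file {filename!r}")
    r = row.iloc[0]
    return {
        "Source": str(r["individual"]),
        "Type": "SNV",
        "Platform_class": "sequencing",
        "Platform_name": str(r["platform"]),
    }
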