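"""Bundled chromosome-sizes tables and species resolution."""

from __future__ import annotations

from importlib import resources

SPECIES_ALIASES = {
    "mouse": "mm10",
    "mm10": "mm10",
    "human": "hg38",
    "hg19": "hg19",
    "hg38": "hg38",
}


def supported_species() -> list[str]:
    return sorted(SPECIES_ALIASES)


def load_chrom_sizes(species_or_path: str) -> dict[str, int]:
    """Chromosome sizes by species alias or from a two-column sizes file."""
    key = species_or_path.lower()
    if key in SPECIES_ALIASES:
        ref = resources.files("chromstate.data").joinpath(
            f"{SPECIES_ALIASES[key]}.chrom.sizes"
        )
        text = ref.read_text()
    else:
        with open(species_or_path) as fh:
            text = fh.read()
    sizes: dict[str, int] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        chrom, length = line.split()[:2]
        sizes[chrom] = int(length)
    return sizes
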