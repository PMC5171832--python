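"""Construction of the single 90-nt recombineering oligo per gene.

One oligo converts the generic tet-sacB landing strain into a gene-specific
tCRISPRi strain in one recombineering step: 35 nt of homology to the sgRNA
cassette, the 20-nt spacer, and 35 nt of homology on the other side
(35 + 20 + 35 = 90 nt).

The homology arms are strain-specific constants of the cassette locus and are
required configuration with no default; the test suite ships a synthetic
placeholder pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from tcrispri.genome_io import reverse_complement

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class OligoConfig:
    """Cassette-specific homology arms and output-strand choice.

    emit_reverse_complement selects the opposite strand of the whole 90-mer,
    for matching a lagging-strand recombineering convention.
    """

    homology5: str
    homology3: str
    emit_reverse_complement: bool = False

    def __post_init__(self) -> None:
        for name, arm in (("homology5", self.homology5), ("homology3", self.homology3)):
            if len(arm) != 35:
                raise ValueError(f"{name} must be exactly 35 nt, got {len(arm)}")
            if not set(arm) <= _ACGT:
                raise ValueError(f"{name} contains non-ACGT characters: {arm!r}")


def build_oligo(spacer: str, config: OligoConfig) -> str:
    """Return the 90-nt oligo homology5 + spacer + homology3.

    The spacer occupies positions 36-55 (1-based) of the forward-orientation
    product; the whole oligo is reverse-complemented when the config says so.
    """
    if len(spacer) != 20:
        raise ValueError(f"spacer must be exactly 20 nt, got {len(spacer)}")
    if not set(spacer) <= _ACGT:
        raise ValueError(f"spacer contains non-ACGT characters: {spacer!r}")
    oligo = config.homology5 + spacer + config.homology3
    if config.emit_reverse_complement:
        oligo = reverse_complement(oligo)
    return oligo


def batch_oligos(
    design: pd.DataFrame, config: OligoConfig, path: str | Path | None = None
) -> str:
    """Build one FASTA record per qualifying gene in a design table.

    Rows whose status is not "ok" (no qualifying sgRNA, failed validation)
    are omitted with a log message. Record ids are "<gene>_tCRISPRi_oligo".
    Returns the FASTA text; writes it when a path is given.
    """
    records = []
    for _, row in design.iterrows():
        if row.get("status") != "ok" or not row.get("spacer"):
            logger.info("no oligo for gene %s (status: %s)", row["gene"], row.get("status"))
            continue
        records.append((f"{row['gene']}_tCRISPRi_oligo", build_oligo(row["spacer"], config)))
    if not records:
        logger.warning("design table yielded no qualifying oligos")
    text = "".join(f">{name}\n{seq}\n" for name, seq in records)
    if path is not None:
        Path(path).write_text(text)
    return text
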