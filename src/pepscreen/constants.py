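"""Shared constants: the canonical alphabet and the reference peptides of the screen."""

# Canonical 20-letter amino-acid alphabet, alphabetical by one-letter code.
# Non-canonical codes (X, U, B, Z, ...) are rejected at parse time.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# CD44v6-inhibiting parent peptides used for the single-substitution scan:
# two 5-mers and two 14-mers (human and murine background).
PARENT_PEPTIDES: tuple[str, ...] = (
    "NRWHE",
    "NGWQG",
    "KEQWFGNRWHEGYR",
    "QETWFQNGWQGKNP",
)

# Influenza haemagglutinin epitope used as the on-chip quality control;
# also the strongest cell-adhesive sequence in the screen.
HA_EPITOPE: str = "YPYDVPDYA"

# Average mass of one water molecule (Da), added once per peptide bond chain.
WATER_MW: float = 18.0153

BLANK_ID: str = "BLANK"


def validate_sequence(seq: str, *, allow_empty: bool = False, context: str = "sequence") -> str:
    """Check that *seq* uses only the canonical alphabet; return it unchanged.

    Raises ValueError naming the first offending 1-based position.
    """
    if not seq:
        if allow_empty:
            return seq
        raise ValueError(f"{context} must be non-empty")
    for i, aa in enumerate(seq, start=1):
        if aa not in AA_INDEX:
            raise ValueError(
                f"{context} contains non-canonical residue {aa!r} at position {i}"
            )
    return seq
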