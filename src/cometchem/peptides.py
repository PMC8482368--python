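"""Built-in peptide definitions.

The two histone tail peptides the workflow was developed on:

* H3(18-26) ``KQLATKAAR`` with modifiable lysines K18 and K23 (2 sites,
  9 isotopologues, 6 MS1-resolvable channels at z = 2);
* H4(4-17) ``GKGGKGLGKGGAKR`` with K5, K8, K12 and K16 (4 sites,
  81 isotopologues, 15 MS1 channels).

Additional peptides can be declared in the YAML config (see :mod:`.io`).
"""

from __future__ import annotations

from .mass_model import PeptideSpec

H3_18_26 = PeptideSpec(
    name="H3_18_26",
    sequence="KQLATKAAR",
    sites=(0, 5),
    residue_offset=18,
)

H4_4_17 = PeptideSpec(
    name="H4_4_17",
    sequence="GKGGKGLGKGGAKR",
    sites=(1, 4, 8, 12),
    residue_offset=4,
)

PEPTIDES: dict[str, PeptideSpec] = {p.name: p for p in (H3_18_26, H4_4_17)}


def get_peptide(name: str) -> PeptideSpec:
    try:
        return PEPTIDES[name]
    except KeyError:
        known = ", ".join(sorted(PEPTIDES))
        raise KeyError(f"unknown peptide {name!r}; built-ins: {known}") from None
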