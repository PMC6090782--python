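"""Primer-design templates for circular RNAs.

Because a circRNA is covalently closed, its only circle-specific PCR
product crosses the backsplice seam. The seam of a linearized spliced
sequence sits between its last and first base — useless for a linear
design engine — so the template is the half-rotation of the spliced
sequence, which places the seam near the template center where both
primers can be placed around it.

Two modes:

* ``divergent`` — the engine's target region is the two bases straddling
  the seam, so any designed product must cover it; primers convergent on
  the template are divergent on the genome.
* ``junction_spanning`` — additionally one primer itself must overlap the
  seam, which is the stricter, circle-specific design.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

from .models import (
    CircKitError,
    MODE_DIVERGENT,
    MODE_JUNCTION,
    SplicedSequence,
    TemplateRecord,
)

DEFAULT_MIN_TEMPLATE_LEN = 60
DEFAULT_PRODUCT_SIZE_RANGE = (70, 250)


def build_template(
    spliced: SplicedSequence,
    mode: str = MODE_DIVERGENT,
    min_length: int = DEFAULT_MIN_TEMPLATE_LEN,
    product_size_range: tuple[int, int] = DEFAULT_PRODUCT_SIZE_RANGE,
) -> TemplateRecord:
    """Rotate a spliced sequence into a design template.

    The template is ``S[m:] + S[:m]`` with ``m = len(S) // 2``; the seam
    then sits immediately before offset ``junction_pos = len(S) - m``.
    """
    if mode not in (MODE_DIVERGENT, MODE_JUNCTION):
        raise ValueError(f"unknown template mode {mode!r}")
    seq = spliced.sequence.upper()
    length = len(seq)
    if length < min_length:
        raise CircKitError(
            f"{spliced.circ_id or 'sequence'}: spliced sequence of {length} nt "
            f"is below the {min_length} nt template minimum; consider the "
            "genomic sequence or a smaller minimum"
        )
    m = length // 2
    template = seq[m:] + seq[:m]
    junction_pos = length - m
    lo, hi = product_size_range
    constraints = {
        "target_start": junction_pos - 1,
        "target_length": 2,
        "product_size_range": (min(lo, length), min(hi, length)),
    }
    if mode == MODE_JUNCTION:
        constraints["overlap_junction"] = junction_pos
    return TemplateRecord(
        circ_id=spliced.circ_id,
        template_seq=template,
        junction_pos=junction_pos,
        mode=mode,
        constraints=constraints,
    )


def template_to_circle(template: TemplateRecord, template_pos: int) -> int:
    """Map a template offset back to a coordinate on the spliced circle."""
    length = len(template.template_seq)
    if not (0 <= template_pos < length):
        raise ValueError("template position out of range")
    m = length - template.junction_pos  # rotation amount
    return (template_pos + m) % length


def write_design_input(
    template: TemplateRecord, path: Union[str, Path]
) -> None:
    """Serialize a template as a Boulder-IO record for a design engine.

    The record carries the template, a 2-base target spanning the seam,
    the product-size range, and (for junction-spanning mode) the
    junction-overlap position.
    """
    lo, hi = template.constraints["product_size_range"]
    lines = [
        f"SEQUENCE_ID={template.circ_id}|{template.mode}",
        f"SEQUENCE_TEMPLATE={template.template_seq}",
        (
            f"SEQUENCE_TARGET={template.constraints['target_start']},"
            f"{template.constraints['target_length']}"
        ),
        f"PRIMER_PRODUCT_SIZE_RANGE={lo}-{hi}",
    ]
    if template.mode == MODE_JUNCTION:
        lines.append(
            f"SEQUENCE_OVERLAP_JUNCTION_LIST={template.constraints['overlap_junction']}"
        )
    lines.append("=")
    Path(path).write_text("\n".join(lines) + "\n")


def read_design_input(path: Union[str, Path]) -> dict:
    """Parse a Boulder-IO record back into a tag/value dict (for round-trips)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if line == "=":
            break
        if "=" in line:
            key, _, value = line.partition("=")
            out[key] = value
    return out
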