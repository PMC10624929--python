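"""Integration-site mapping from denaturing-gel product lengths.

A half-site strand-transfer product on the labeled target strand has
length

    product = vDNA + site (+ 2 nt when the fragment carries two dyes),

so the integration position follows by subtraction: the transferred
viral strand contributes its full length (38 nt for the unlabeled
construct, 30 nt for the transferred-strand-labeled construct) and a
fragment carrying both a donor and an acceptor dye runs ~2 nt slow.
Positions are 1-based nucleotide counts from an explicitly named anchor
end of the labeled strand.

Concerted integration places the second strand-transfer event 4 bp away
across the major groove on the opposite strand; when the phosphate
required for that second reaction falls inside the lesion (nick/gap)
interval, only a half-site product is chemically possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "GelProduct",
    "IntegrationCall",
    "map_band_to_site",
    "predict_partner_site",
    "classify_product",
    "band_fraction",
    "product_length_from_site",
]

DONOR_DYE = "Cy3"
ACCEPTOR_DYE = "Cy5"
MARKER_DYE = "AF488"
DEFAULT_SPACING = 4  # bp between the two concerted strand-transfer events


@dataclass(frozen=True)
class GelProduct:
    """One band from a denaturing gel of strand-transfer reaction products."""

    product_length: int          # nt
    fluorophores: frozenset      # subset of {Cy3, Cy5, AF488}
    strand: str                  # which target strand carries the label
    vdna_length: int             # nt of the transferred viral strand

    def __post_init__(self) -> None:
        if self.product_length <= 0 or self.vdna_length <= 0:
            raise ValueError("lengths must be positive integers")

    @property
    def n_dyes(self) -> int:
        """FRET dyes (donor/acceptor) on the fragment; the marker does not
        shift mobility in the calibrated ladder."""
        return len(self.fluorophores & {DONOR_DYE, ACCEPTOR_DYE})


@dataclass
class IntegrationCall:
    """A mapped integration position on one target strand."""

    position: int                 # nt from the anchor end, 1-based
    product_class: str            # half-site | concerted-candidate | alcoholysis | unknown
    strand: str
    anchor_end: str               # "3'" or "5'" of the labeled strand
    spacing: int = DEFAULT_SPACING
    partner_position: Optional[int] = None
    note: str = ""


def product_length_from_site(site: int, vdna_length: int, n_dyes: int, dual_dye_correction: int = 2) -> int:
    """Forward constructor: expected band length for a half-site event.

    Exact inverse of :func:`map_band_to_site`.
    """
    corr = dual_dye_correction if n_dyes == 2 else 0
    return site + vdna_length + corr


def map_band_to_site(
    product: GelProduct,
    dual_dye_correction: int = 2,
    anchor_end: str = "3'",
) -> IntegrationCall:
    """Map a strand-transfer band length to an integration position.

    position = product_length - vdna_length - correction, where the
    ~2 nt gel-mobility correction applies only when the fragment carries
    exactly two FRET dyes.  A non-positive position means the band is not
    a strand-transfer product.
    """
    corr = dual_dye_correction if product.n_dyes == 2 else 0
    position = product.product_length - product.vdna_length - corr
    if position <= 0:
        raise ValueError(
            f"{product.product_length} nt band is not a strand-transfer product "
            f"(vDNA {product.vdna_length} nt, correction {corr} nt)"
        )
    return IntegrationCall(
        position=position,
        product_class="half-site",
        strand=product.strand,
        anchor_end=anchor_end,
    )


def predict_partner_site(
    call: IntegrationCall,
    duplex_length: int,
    lesion_interval: Optional[tuple] = None,
    spacing: int = DEFAULT_SPACING,
) -> IntegrationCall:
    """Predict the second (concerted) strand-transfer position.

    Positions are first placed on a common duplex axis (1..duplex_length,
    counted from the 5'-end of the lesion-containing strand); the partner
    event sits ``spacing`` bp away on the opposite strand, toward the
    lesion side.  ``lesion_interval`` gives the duplex coordinates
    (inclusive) where the lesion interrupts the phosphate backbone of the
    opposite strand; a partner falling inside it has no phosphate to
    attack and the call degrades to half-site ("infeasible").

    Returns a copy of the call with ``partner_position`` set (duplex
    coordinates) or with ``note`` explaining infeasibility.
    """
    if spacing <= 0:
        raise ValueError("spacing must be a positive number of base pairs")
    # duplex coordinate of the first event
    if call.anchor_end == "3'":
        duplex_pos = call.position  # 3'-end of the undamaged strand aligns
        # with the 5'-end of the lesion strand on the duplex axis
    else:
        duplex_pos = duplex_length - call.position + 1
    partner = duplex_pos - spacing
    out = IntegrationCall(
        position=call.position,
        product_class=call.product_class,
        strand=call.strand,
        anchor_end=call.anchor_end,
        spacing=spacing,
    )
    if partner < 1 or partner > duplex_length:
        out.note = "partner position falls outside the duplex; half-site"
        return out
    if lesion_interval is not None and lesion_interval[0] <= partner <= lesion_interval[1]:
        out.note = (
            "partner phosphate falls inside the lesion interval "
            f"[{lesion_interval[0]}, {lesion_interval[1]}]; no phosphate bond for "
            "the second strand transfer; half-site"
        )
        return out
    out.partner_position = partner
    out.product_class = "concerted-candidate"
    return out


def classify_product(
    product: GelProduct,
    substrate_length: int,
    known_alcoholysis_lengths: Sequence[int] = (),
    vdna_labeled: bool = False,
) -> str:
    """Classify a gel band: unreacted, alcoholysis, half-site or unknown.

    * a band at the intact labeled-strand length is unreacted substrate;
    * a band shorter than the intact strand that cannot contain the viral
      DNA (no donor dye when the viral DNA is labeled, or a known
      alcoholysis length) is an endonucleolytic alcoholysis candidate;
    * a band longer than vDNA that yields a positive site is a half-site
      strand-transfer product;
    * anything else is "unknown" — never dropped silently.
    """
    L = product.product_length
    if L == substrate_length:
        return "unreacted"
    if L < substrate_length:
        if vdna_labeled and DONOR_DYE not in product.fluorophores:
            return "alcoholysis"
        if L in set(known_alcoholysis_lengths):
            return "alcoholysis"
    if L > product.vdna_length:
        corr = 2 if product.n_dyes == 2 else 0
        if L - product.vdna_length - corr > 0:
            return "half-site"
    return "unknown"


def band_fraction(band_intensity: float, lane_total: float) -> float:
    """Integration efficiency: 100 * band / lane (fractional band intensity)."""
    if lane_total <= 0:
        raise ValueError("lane total must be positive")
    if band_intensity < 0:
        raise ValueError("band intensity must be non-negative")
    if band_intensity > lane_total:
        raise ValueError("band intensity exceeds lane total")
    return 100.0 * band_intensity / lane_total
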