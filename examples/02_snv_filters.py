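"""Apply the single-cell SNV confirmation filters to read counts.

A bulk-confirmed SNV is accepted in a cell only with >= 3 supporting reads
that are strictly more than 1% of the reads at the position, and only if
the observed base change matches the bulk call.
"""

from clonotrace import SiteCounts, SnvSite, call_snv_presence, check_bulk_concordance

site = SnvSite("SNV_017", chrom="chr12", pos=25398284, ref_base="C", alt_base="T")

for alt, depth, note in [
    (3, 100, "3 reads at 3% VAF: passes both filters"),
    (3, 300, "3 reads at exactly 1%: fails the strict >1% rule"),
    (2, 10, "20% VAF but only 2 reads: fails the 3-read minimum"),
    (0, 0, "no coverage"),
]:
    counts = SiteCounts(site.assay_id, "cell_0001", alt, depth)
    call = call_snv_presence(counts, site)
    print(f"alt={alt:3d} depth={depth:3d} -> call={call}   ({note})")

# bulk concordance: the single-cell site must match the bulk manifest exactly
bulk = {site.assay_id: site}
discordant = SnvSite("SNV_017", "chr12", 25398284, "C", "G")
print("concordant site accepted:", check_bulk_concordance(site, bulk))
print("different base change accepted:", check_bulk_concordance(discordant, bulk))
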