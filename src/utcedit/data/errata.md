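# Errata for the packaged ledgers

The two shipped ledgers (`candidate_sites.tsv`, `validated_sites.tsv`) are
verbatim transcriptions of the source study's printed tables.  They contain
internal inconsistencies, catalogued here; the code never corrects the
fixtures silently.

1. **Position ↔ gene pairing is swapped between the two ledgers.**
   The candidate ledger pairs position 14198871 with AT3G41768 (row 13) and
   7191297 with AT2G16586 (row 55); the validated ledger pairs 14198871 with
   AT2G16586 (row 1) and 7191297 with AT3G41768 (row 4).  Both are retained
   as printed; no reconciliation is attempted.

2. **AT3G41768 editing efficiency.** The study's narrative quotes 45.65%,
   while the validated ledger prints 45.54 (12-day sample).  The ledger
   value is shipped; both values are noted here.

3. **U-to-C gene counts disagree across summaries.** The conversion-spectrum
   summary reports 50 genes with U-to-C conversion, the gene-list
   intersection figure reports 54 U-to-C variant genes, and the candidate
   ledger itself contains 53 distinct gene IDs (56 rows with 3 duplicated
   genes: AT2G07709, AT2G16586, AT5G52530).  All three counts are retained.

4. **Validated gene list.** The results text lists AT5G02670 among the
   seven validated genes; the discussion text lists AT1G05670 instead.  The
   validated ledger (AT5G02670) is treated as authoritative.
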