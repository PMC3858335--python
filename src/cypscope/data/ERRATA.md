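# Catalog errata

The shipped catalog (`table1_caucasian.tsv`) transcribes the printed
Caucasian star-allele table verbatim. The source article's running text
disagrees with that table in a few places; where they conflict, the table
value is authoritative for this package. Known discrepancies:

- CYP2A6*1B: text reports 30.0%, table prints 32.6% (table used).
- CYP2A6*2: text reports 8.0% in Caucasians, table prints 2.3% (table used).
- CYP2C9*2: text reports 16.0%; the table prints a genotype breakdown
  ("19.0% *1/*2 1.6% *2/*2 1.8 % *2/*3"); the loader takes the first listed
  percentage (19.0, the *1/*2 carrier frequency) as the scalar and keeps the
  cell verbatim in the raw field.
- CYP2D6: text claims 11 alleles with known impact; the table prints 10 rows.
  The eleventh, CYP2D6*2A (32.4%), appears only in the text and is therefore
  not part of the catalog.

The SNP table (`table2_1000g.tsv`) likewise reproduces the printed rows,
including duplicate rsIDs (rs28399499 with two distinct amino-acid changes,
rs11572103 printed twice) and the rsID rs1126743 for CYP4A11, which the
running text cites as "rs112743" (probable typo).
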