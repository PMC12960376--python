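LOCUS       TOY1                    1119 bp    DNA              UNK 01-JAN-1980
DEFINITION  synthetic gene model for TOY1.1.
ACCESSION   TOY1
VERSION     TOY1.1
KEYWORDS    .
SOURCE      .
  ORGANISM  .
            .
FEATURES             Location/Qualifiers
     gene            1..1119
                     /gene="TOY1"
     mRNA            join(1..120,211..390,484..643,740..889,980..1119)
                     /gene="TOY1"
                     /transcript_id="TOY1.1"
     CDS             join(51..120,211..390,484..643,740..889,980..1019)
                     /gene="TOY1"
                     /transcript_id="TOY1.1"
                     /translation="MGNSDTVALLPPDEFIAYVYSRAPPLRLGRIITTIGAVSNPGRLA
                     YANSLRLYIGRAEAHNRILIQLGFSCGSDWRHIFYNAKYMLGDCIGARKLVRSKEKLTR
                     INDSHKTSLKQTHPLYQAQQTGQTRTRNTSGYYTRHLLQASQGGLFKFPIDSKMYAAIG
                     NEGTPYTCVELTLCQDYGKTTLHGRLLRLGDYTRVT"
ORIGIN
        1 ccctaagcta tactaggcag ctgcagcgtc tggttttact cagtgtgatc atgggtaaca
       61 gtgacacagt agcccttttg ccccctgatg aatttatcgc ctatgtgtac tcgcgggctc
      121 gtccccccta acttcctctc ctctcctttt ttcttttttt tttccccccc ctctcttccc
      181 tccctcccct tttttctctc cttccctcag ccccgctgag actagggcga attatcacaa
      241 ctataggggc tgtgagcaat ccggggcggc ttgcatacgc gaattcatta cgattatata
      301 taggacgggc tgaagcccat aaccgcatac tgatccaact agggttttcc tgcggaagcg
      361 attggagaca cattttttac aatgccaagt gtccccccta atttcctctc ccctctcctt
      421 ctccttttcc ttctcttcct ctttttccct ctctccccct tccttttccc tctttctctc
      481 cagacatgct gggcgattgc ataggtgcaa gaaaattagt tcggtccaaa gagaaactca
      541 ctaggatcaa tgatagtcac aaaacgtcat tgaagcaaac gcatccactt taccaagctc
      601 agcaaacagg acaaacacgc acgcgaaaca ctagtggcta ctagtccccc ccctaatttt
      661 cccttcctcc ctctcctttt ccccttctct ctctttctct tcttcccctt cctccttctt
      721 tttcctcctt ttcccttagc acccgccatc tcttgcaggc ctcccaggga ggccttttta
      781 agtttcccat cgattccaag atgtatgcag caattggtaa tgaaggcacc ccttatacct
      841 gcgttgagct cactttatgc caagattacg gaaaaacaac cttgcacggg tcccccccct
      901 aacttttctc ctctctcttt ttcttcctcc ttttctcccc ccccctctcc ttcttcctct
      961 cctcctttcc ctttctcaga cgtcttctca gattaggaga ttacacccgg gtcacttaat
     1021 ttatgcttga gaaaatcaac ccttgtcaca tacatagtgt ttgggtcttc cgtaaacagg
     1081 tgcttggcga gttccgcgaa acactttgag gtcagcgcc
//
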