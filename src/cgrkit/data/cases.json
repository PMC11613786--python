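{
  "reference": {
    "assembly": "T2T-CHM13v2.0",
    "contig": "chr21",
    "accession": "NC_060945.1",
    "length": 45090682,
    "centromere": [10900000, 11300000]
  },
  "cases": {
    "RD_P505": {
      "segments": "rd_p505.tsv",
      "karyotype_cytoband": "46,XY,der(21)(pter::p11.2->p11.2::q22.3->q22.3::p11.2->p12::q22.11->q22.11::q22.2->q22.2::q22.11->q22.11::p13->p13::p11.2->q21.3::q21.2->q22.13::q22.12->qter)",
      "karyotype_seq": "NC_060945.1:g.[pter_(8500000_9500000)delins[7309183_(8500000_9500000)inv;41208203_45090682;3280083_7309182inv:29450256_30482559;37439494_38243038;30739588_32660588inv;pter_23765838inv];24915464_24915465ins23765839_24915464;35258903_352589034ins33708435_35258903]"
    },
    "RD_P26": {
      "segments": "rd_p26.tsv",
      "karyotype_cytoband": "46,XX,der(21)(::p12->p13::p13->p13::p11.2->q22.3::q22.3->q22.3::)",
      "karyotype_seq": "NC_060945.1:g.[pter_(8275500_8277000)delins[2754001_3885184inv;(329000_331000)_532438]::40385031_qterdelins[41802371_42715704inv]]"
    },
    "RD_P01": {
      "segments": "rd_p01.tsv",
      "karyotype_cytoband": "46,XX,der(21)(pter->p13::q21.3->q21.3::q21.3->q21.3::p12->q11.2::q21.3->q21.3::q21.3->q21.3::q22.11->q22.11::p11.2->?::q21.3->q21.3::q22.11->q21.3::q22.11->q22.11::q22.3->q22.3::q22.3->q22.3::q22.13->q22.12::q22.3->q22.3::q22.2->qter)",
      "karyotype_seq": "NC_060945.1:g.[2836888_3100034delins[25290884_25865801inv;24610784_25303024];14851664_37237425delins[26799626_26934775inv;26642007_26776417inv;29463413_29673698;10971588_?;25713476_27417473;27809327_31179763inv;31172424_31653157inv;44694487_44862839inv;42358829_42440338inv;34549576_36841750inv;43489001_43505695]]"
    }
  }
}
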