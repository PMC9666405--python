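gene: Tcf4
species: mouse
assembly: mm10
contig: chr18
strand: "+"
locus: [69341000, 69668600]
constitutive_chain: ["10", "11", "12", "13", "14", "15", "16", "17", "18", "19", "20"]
splice_features:
  delta:
    skipped_exons: ["8", "9"]
  plus_minus:
    exon: "8"
    plus_variant: "II"
exons:
  - {name: "1", class: five_prime, start: 69341000, end: 69341150}
  - {name: "2", class: five_prime, start: 69344500, end: 69344620}
  - {name: "3", class: five_prime, start: 69347270, end: 69347370}
  - {name: "3b", class: five_prime, start: 69352000, end: 69352110}
  - {name: "3c", class: five_prime, start: 69356500, end: 69356595}
  - {name: "3d", class: five_prime, start: 69361000, end: 69361130}
  - {name: "3e", class: five_prime, start: 69365800, end: 69365885}
  - {name: "3f", class: five_prime, start: 69369400, end: 69369490}
  - name: "4"
    class: internal
    start: 69380000
    end: 69380090
    start_extensions: {c: 220}
  - {name: "4a", class: five_prime, start: 69390000, end: 69390095}
  - {name: "5", class: internal, start: 69405000, end: 69405085}
  - {name: "5a", class: five_prime, start: 69420000, end: 69420100}
  - {name: "6", class: internal, start: 69438000, end: 69438092}
  - {name: "7", class: internal, start: 69455000, end: 69455088}
  - {name: "7a", class: five_prime, start: 69470000, end: 69470105}
  - name: "7b"
    class: internal
    start: 69481000
    end: 69481130
    start_extensions: {II: 250}
  - name: "8"
    class: internal
    start: 69500000
    end: 69500132
    splice_variants:
      - {label: II, site: acceptor, offset: -12}
  - {name: "9", class: internal, start: 69520000, end: 69520075}
  - {name: "10", class: internal, start: 69560000, end: 69560086}
  - {name: "10a", class: five_prime, start: 69593500, end: 69593610}
  - {name: "10b", class: five_prime, start: 69601000, end: 69601105}
  - {name: "11", class: internal, start: 69610000, end: 69610104}
  - {name: "12", class: internal, start: 69616000, end: 69616088}
  - {name: "13", class: internal, start: 69622000, end: 69622154}
  - {name: "14", class: internal, start: 69628000, end: 69628101}
  - {name: "15", class: internal, start: 69634000, end: 69634120}
  - {name: "16", class: internal, start: 69640000, end: 69640096}
  - {name: "17", class: internal, start: 69646000, end: 69646140}
  - {name: "18", class: internal, start: 69652000, end: 69652123}
  - {name: "18a", class: internal, start: 69655000, end: 69655075}
  - {name: "19", class: internal, start: 69658000, end: 69658118}
  - {name: "20", class: three_prime, start: 69663000, end: 69668600}
isoforms:
  - name: TCF4-B
    initiating_exon: "3"
    alt_initiating_exons: ["3b", "3c", "3d", "3e", "3f"]
    diagnostic_junctions: ["3-4", "3b-4", "3c-4", "3d-4", "3e-4", "3f-4"]
    transcript_exons: ["3", "4", "5", "6", "7", "8", "9", "10", "11", "12", "13", "14", "15", "16", "17", "18", "19", "20"]
    annotated: true
  - name: TCF4-C
    initiating_exon: "4a"
    diagnostic_junctions: ["4a-5"]
    extended_exon: 4c
    transcript_exons: ["4a", "5", "6", "7", "8", "9", "10", "11", "12", "13", "14", "15", "16", "17", "18", "19", "20"]
    annotated: true
    provisional: true
  - name: TCF4-D
    initiating_exon: "8"
    diagnostic_junctions: ["7b-8"]
    extended_exon: 7bII
    transcript_exons: ["7b", "8", "9", "10", "11", "12", "13", "14", "15", "16", "17", "18", "19", "20"]
    annotated: true
  - name: TCF4-A
    initiating_exon: "10a"
    diagnostic_junctions: ["10a-11"]
    transcript_exons: ["10a", "11", "12", "13", "14", "15", "16", "17", "18", "19", "20"]
    annotated: true
  - name: TCF4-I
    initiating_exon: "10b"
    diagnostic_junctions: ["10b-11"]
    transcript_exons: ["10b", "11", "12", "13", "14", "15", "16", "17", "18", "19", "20"]
    annotated: true
    provisional: true
junctions:
  - {up: "1", down: "4"}
  - {up: "2", down: "4"}
  - {up: "3", down: "4", isoform: TCF4-B}
  - {up: "3b", down: "4", isoform: TCF4-B}
  - {up: "3c", down: "4", isoform: TCF4-B}
  - {up: "3d", down: "4", isoform: TCF4-B}
  - {up: "3e", down: "4", isoform: TCF4-B}
  - {up: "3f", down: "4", isoform: TCF4-B}
  - {up: "4", down: "5"}
  - {up: "4a", down: "5", isoform: TCF4-C}
  - {up: "5", down: "6"}
  - {up: "5a", down: "6"}
  - {up: "6", down: "7"}
  - {up: "7", down: "8", variant: I}
  - {up: "7", down: "8", variant: II}
  - {up: "7", down: "10", feature: delta}
  - {up: "7a", down: "8", variant: I}
  - {up: "7a", down: "8", variant: II}
  - {up: "7b", down: "8", variant: I, isoform: TCF4-D}
  - {up: "7b", down: "8", variant: II, isoform: TCF4-D}
  - {up: "8", down: "9"}
  - {up: "9", down: "10"}
  - {up: "10", down: "11"}
  - {up: "10a", down: "11", isoform: TCF4-A}
  - {up: "10b", down: "11", isoform: TCF4-I}
  - {up: "11", down: "12"}
  - {up: "12", down: "13"}
  - {up: "13", down: "14"}
  - {up: "14", down: "15"}
  - {up: "15", down: "16"}
  - {up: "16", down: "17"}
  - {up: "17", down: "18"}
  - {up: "18", down: "19"}
  - {up: "18", down: "18a"}
  - {up: "18a", down: "19"}
  - {up: "19", down: "20"}
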