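"""Synthetic terminal-domain templates packaged as fixtures.

These N- and C-terminal domain sequences are SYNTHETIC stand-ins constructed
once with a seeded generator (clade base sequence + ~8% per-family
substitutions, giving >70% within-clade identity and near-random
between-clade identity). They emulate the conserved/diverged structure of
real spidroin terminal domains without redistributing any natural sequence.
NTD templates are 150 aa (450 nt), CTD templates 100 aa (300 nt).
"""

FAMILY_CLADE = {
    "MaSp1": "MaSp1",
    "MaSp2": "MaSp2",
    "MaSp3": "MaSp3",
    "MaSp4": "MaSp2",
    "MaSp5": "MaSp5",
    "MiSp1B": "MiSp",
    "MiSp1C": "MiSp",
    "MiSp1D": "MiSp",
    "Flag": "Flag",
}


NTD = {
    "MaSp1": "TDLDAAELNGLSSENYPMEASTSAKIALESEKKNVEPIAMALSLRCQRKNMDSIPLSTSRGIEQGIKVIDNKKEKMRKGLVPQDDRNGYNQDRTVQTCGMIAQAQNDPRMSAAGRASLFLDAEQWSGGFSQEPTAGWPQQVGQRFAAEIF",
    "MaSp2": "GNALQAADTAAGFTNIEVSYSRLGAEQRKSSVSGNRKGFNFMGVQSVATAVCMYMQAELSANASQEEQSIQRWRLVRGAVVQDEANAGNTRPDFQTLLDGTNAAQSRVSSWSGVEQNVPEDLERFATPTTQEGSNGDKLVSVSIYIMDAV",
    "MaSp3": "NSQIIASAGQKGDVMKYETSGCASVKDRQLYDGWGADTILCTKGVAGGRRLLAQSFWGRASEYNAADSCQQSGYVVHWMEEVQCLEVAGWVRNEDCGRRGQDRDTHALTQEYAIDYVTTMGQGILDVKYKPIITGTETQESKIMHPQLHP",
    "MaSp4": "GNALQAADWAAGFTVIEVSYSRLGAEQRKSSVSGNRKGLNMMGFQSVATAVCMYMQAELSANASQEEQSIQRWRLKPGYVVQDEANAGNTRPDFQTLLDGTNAAQRRVTSWSGVEQNVPEKLERFATGTTQEGSNFDKLVSVSIDIMVAV",
    "MaSp5": "AATYLTGQGPIGAFDPQQAPIQRQWDFLMEGGQGNLRDSPAGTLATNKHGNRFCNFRDSHAGSSEPAQACLITDNSEASQKEVQPEEQFSLPGFRQSAQLGEEVRAKQKTAKYPVVQQAFALVRHYQPVRVGDLQHRPQPSDSSRMLSIR",
    "MiSp1B": "PTRTYNVSDVQGIASEMISSVSPARFTMMRGKNEGGVEEQYIGKLQGTMCGSQQNTSHAEQAGFAKHDQQYVMGCLLPSYYAEMARCFNVQVNREELVQGQYQGLRQEGEVAMEAGKFQNVKSFYFAENYVRLAEDLEEVTLQPLIGGVV",
    "MiSp1C": "PTRTYNVFDVQEIASEMDSSVSPARATMMRGKNEGGHEEQDIGKLQGTMQGQQQNTSQAEQAQFRKHQQQYVIGCLLPSYLSEMARKFNGQVYETELTQGQYQGLRHQGEVAMEATKFQPVKSGYFAENSLRLGEDLEEVTLSPLIDGVF",
    "MiSp1D": "PTRTNNVSDVQEIASEMDSSVPPARATMMRGGNEGGVEEQYIFKLQGTQLGDQQNTSQAEQAGFAKHQQQPVIGCLLPSYLAEMARKCNVQVNREEQIQGQYQGLRQEGEVAMPAGKFQNVKSGYFAENYLRLGEDLEEVTLSPLIGGVV",
    "Flag": "ENWVAHATQWALQKLSGNLLRRSATSRDYQGALWNEAGNGEVELYTVSQLKLETAGKYQWRVFDGSETTGMFRYSSSHPSQPTLDRTEQCQLFDELQMPASTNRVFVAYWLMEELLSPSLEEQVRIGSGQDTAMQLYIWRPAAKYGNRFF",
}
CTD = {
    "MaSp1": "AMDWFHFDFSDLSDHRGFFLDYRVSLTFAFSDFIKQAQGAQHIGKKDSVQSDDRLSANVSGGSKVGLAAQCQEYETGKAFRDRKNLAAAFFEIDNMRVAL",
    "MaSp2": "ATDPTNYEALSCQPVRRHWCSGQLVQGAATKLLQKHSDRTLFCGKIDRWASILFENYLGLSQPCVGVLYDSAGRGYSDEGTDYVQSNFGCTTAISSEDSP",
    "MaSp3": "IDIGSILGVAMASSIVFGNSIALNGASWSGYENRLTSLKDNYAIAIQHAASAPGNPLQEAADASLQSEQSTKGWQKVGALLTYIRSRKMQSAERAGDGGV",
    "MaSp4": "AIDDTNYEFLSCQPVRYHWCSGQLVWGAATKLLQKHCDRRLFCGSIDRWAMILFENGLGLSQPCVGVLSDSAGRGNSDEGTDLVQSNVGATTAISSEDSP",
    "MaSp5": "NQADKSLSDCLYHSNAAEKITIENEGYWTQDLSSSEVANGRGLERWLLKQKNREFYFCTWKLVQDETLNQVFGRGMNNIQHKGTDGASLINSGNALLRYV",
    "MiSp1B": "QYPIESCYAKSANINGDQGRDYESFEVRAHLVSRGLELLTNLLAALANFFVLMEKAGWACQDEQTGQLFSAGHLEETCIEPNQGEVADGKLRYLDVEKLA",
    "MiSp1C": "QDPIESCYLKSANMHGGQGRDYIDFEYRAHAVSRGLELLTNLLAALANFFQLMEKAGWAESDEQTFVLHSVGHLEENCGEPVQGEGADGTLRYLDVEKLI",
    "MiSp1D": "QDPIESCYLKSANITGGQGRDYESFEYRAHLVSRGLELLTNLLAALWNFFQLMEKAGWAESDEQTFQLFSAGHLEETCKEPVQGEVADGTLRYDDVEKLA",
    "Flag": "QEADQRFTQFSSDVSQVKRDESTQADAKVQEVRSTGNHESNIGIMRGEIISSHSSDRDFRSQHAKPNQDHGNSALADFVLDLLQVVSKQATRHGYASEVN",
}
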