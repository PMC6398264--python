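D64	http://purl.obolibrary.org/obo/DOID_2355
E03	http://purl.obolibrary.org/obo/DOID_1459
E11	http://purl.obolibrary.org/obo/DOID_9352
I10	http://purl.obolibrary.org/obo/DOID_10763
I25	http://purl.obolibrary.org/obo/DOID_3393
I48	http://purl.obolibrary.org/obo/DOID_0060224
J18	http://purl.obolibrary.org/obo/DOID_552
J44	http://purl.obolibrary.org/obo/DOID_3083
J45	http://purl.obolibrary.org/obo/DOID_2841
K21	http://purl.obolibrary.org/obo/DOID_8534
K35	http://purl.obolibrary.org/obo/DOID_8337
K50	http://purl.obolibrary.org/obo/DOID_8778
K51	http://purl.obolibrary.org/obo/DOID_8577
K52	http://purl.obolibrary.org/obo/DOID_0060180
K56	http://purl.obolibrary.org/obo/DOID_8437
K57	http://purl.obolibrary.org/obo/DOID_13250
K58	http://purl.obolibrary.org/obo/DOID_9778
K80	http://purl.obolibrary.org/obo/DOID_9810
K90.0	http://purl.obolibrary.org/obo/DOID_10608
M19	http://purl.obolibrary.org/obo/DOID_8398
N39.0	http://purl.obolibrary.org/obo/DOID_13148
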