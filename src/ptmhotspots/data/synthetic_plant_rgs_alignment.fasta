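>AtRGS1
DAKADMYLTWTPKMGLIFYACEYQVFRILAPTQEMGYVEMWTRPARLCFMRMPVQIPNDCQINHFEITKINYINKPKPMQYENKIFCKTCKYYFAQAHLVCQMDTTLWPWYNGDNESWFNAEIVYPNNCIYKFFRAYVNLSMLHKSCARITAWDKYDQRKCMKVQHCNGQVIWMMSSWYEKWHANSRTPDTKTTYAVPLSYMCRFFEEWIDEIHHWVNYHDGCYFKFYEMYMVVSRNNTKWVIKRWCCFKEMMYRGSTQQHRDPWYTSSIRFECLFSWTTNDRMWKEMKNHGDYQKFNINCEQCPIAQPRWQVDWWPRQVWLRWGAEAIAFFPFYEYSSMFAGMCDDPCAKGMWVLNTRINSEMSFEQMHSAFRTKYWTVAAMHVGDDGNDRGGNVIRGSDRTQSSYVKEKMMHNFSMRCTKNANWRSTSSPTTRSHTGCPGVTTKWSDDHSSAKNNTT-
>GmRGS2
GAKVDMYLTWTPKMGLIFYACEYQVFRILAPTQEMGYVHMWTRPARLCFMGMPVQIPNDCQINHFEFTKINYINKPKPMQYANKIFCKQDKYYDIQAHPVCQMDTTLWPWYNGDAGSWFNAEIVYPNSCIYKFFRAYVNLSMLHKSCARITAWGKYDQRKCMKVQHCNGQVPWMMSGWYEKWHANSRTPDTKYTYAVPHSYMCRFFEEWIDEIHHWVNYHDGCYPKFYDMYMVWSRNNTKWCIKRWCCFKEMMYRGSTQQHRDPWYTSSIMFECLFSWTTNDEMQKEMWAHGDYQKFPI-CEELPGQIPRWQVDWWPRQVWLRWGAEAIAFFPFYEYSSMFAGMCHDPFAKLMWVLNTRINSEMSFYQMHSAQRTKYWTVAAMVVGDDGNDRGGRVIRTSDRTQSSYVTEKMMHNFSMRFTKKANMRSTSSITTRSHTGCPGVTTWWSDDHSSAKNNTTF
>SynPlant1
DAYADMYLTNTPKMGLIFYCD---------PTQEVGYVEMWTRPARLCYMRFPVPIPQDCNINHFEITKINYINKAKPMQYENMIFCKTCKRYFATAHHDAQMDTTLWPWYWGDNHSRFN---VYPNNCIYNFCRAYGNLLMLHKSCCRITAWDKYDQRTCMKVQNCNGE-----SSWYEKWHASSRVPDTKTTNAVPTSYECRFIEEWIDLVHHWHNYSLRCYFKFYFMNMSVSRWNTAWVIKRWCCFKEMNYRGSTQQERDPWKTSSIRAECLFSWTTNDRMWKEMVNHGIYTKFQINCEQCPIAQPRWQVDWWPRQVWLRQGAEAIAFFPFYEYSSMFAGMCDDVCAKGGWVLNTRDNSEMSFEQMHSFPSTKYWTVAAMHVGDDGNDRGGNVIRRSDRTQSSYVKEKMMHNFSLRQTKNASWCSTSSPTTRIHTGHNGVTTKWPDAHSSARNNTTN
>SynPlant2
DAKADPYLTWTPSMCLIFYACEYQVFRILAPTQEMGYIEMWNRPARTPFM------PNNCQINHFEITKINYINKPKPLQYESKGFTKTCKYYFAQAHLFCQMDTTLWPWYNGYCESPFNAEIVY-----------YVNLSMLHKSCARITAWDKYDQRKCMKVQHCNGQVPWMMSSWYEKWHANNRTPDGKTTYAVPLSYMCRFFEEWWDEIHHWVNYNDGCYFKFYEMYMVVSRNNTKWVIKRWFTFKEKMYRGSVQQKRDMWYTSSICFECLFSWTTNDRAWKRMKWHGDYDKFNHNCFQCPAAQPRWQVDWWNRQVWLVWGMEAIAFGPIYEYSSMFGGMCRDPCAKGMRVLNTRINSGMSFEQMHSAFRTYYWTVAAMHVGDDGNDRGGNVYRGSGRTQSSKVKCKMMHNFSMRVTKNANWRSTCSPTTRSHTGCPGVTEKWSDDHSSAKNDRTN
>SynPlant3
DAKADMFMPWTPKVGLIFYACENQVFRILAKTQEDGYVEMWTRPARLLI--------NDCQINHKEITKINYHNKPKPNQYENKIFAKTCKYYFAQAHLVCQMDTTLWPWYNAAHESWFNHEIVYPNNCIYKF----------HKSCARITAWMKYDQRKCMKVQHCNGQVIWMHSSWYRIWHANQRTPDTKHHYAVPLSYHIRMFWEWIDEIMHW--------FKFYEMWLVVSRNVRKIQIKRWCCFKEMMYRGSTQQHRPPWYTSSIVFECLFSWTFNCRMEKEMKNHGDYQKFNINCEQCPIAQPKIQADWWPRQVWLRWGCEAIAFFPFYVYSSMFPMMCDDPCAKGMWVLNTRWMSEMSAEQMHSSFRTSYWTVAAMHVRDDGNVGGKEVIRGSDRTQSSYGKEKMLVNFSMCCTININWRSTSSPTTRSHTGCPVVTTKWSDDHSSAKSNWTN
>SynPlant4
SAKADTYLTWTPKMGLIFYLAPYQVFRILAPTQEMGYVEMWKREQRLPFMRMPVQIPGDCQIPHLCATKINYINKPKPMQYEPVYFCQTCKYYFFQAHLKCSMDTTLWPNYNTDNTSWFNAEIVYPNNLIYKIFCALVELSRFHKSCANITAWDKYDQCKGMKVQHCNGQVLWMMSSWYVKWHANSRTP----TLEVPLSTYCRFFEEWIDEIHHWVNYHDGCYFKFY-------WNSQKWVIKRWCCMKIMMYRGSTQQRRDCWYTSSIRIECLFSWTNNDRMWKEMKNQGIYQKFNDNCEQCPIAQPRLHVDWSPRQVWLRWGAEATHFFPFYEYSSMFDGMCDDPCAKGMYFYNTRINSEMSFESMHSAFRTKYWTVAAMHHGDDGNDPGQNVIRGKDRTQTSYVKEKMMHNFSMRCTKNAGTRSTSSPTTRSHTGCKGVTTKWSDDHQSAKNNTGD
>SynPlant5
DSKADMYMMWTPK------PCEYQVFRILAPTQEAGYVKMWTRTARLCFMNMPVQYDNDCQINHFEITKINYINKPKPMQYECKIFCKTQKY---------DMDTTLWPWYSGDGESWFNAEIIYPNFCIAKFFRAYVNLSMLWKSCARITIWDAYAQRKCMKVQHCNGQEIWMMSSWDEKWHFNSWTG----TYAVPLSYMCRFFEETIDEGHHWVNYHSGCYFKFTEMYMVVSHNNTKWVIVRWCCFKEMMYMGSTQQLRDPWYTCSIRFECLFSWTPNNRMWKEMKVHGDYQKFRINCEQCPIAQPRWQVDWWPRQWWLTWGAEKIAFFPFYEYSSMFAGMCDDHCAKGMWVLNTNINSNMSFEQMHSAERTKYWTVAAMHVVDYGNSQGGMVIRGSYRTQSSYIKNKMMHGPSMRYTKNANWRSTSSLVTRSITGCPGVTTKKSDDHSSAKNNTTW
>SynPlant6
DAKRDMSLTWTPKMGLIFYACEYQVFRILAPTQEMGCVERYTRPARLCFMDMYVQEPWHCQINHFEITKMNYINKPKPMQYENKIFCKTCKYYFDQAHLVCQDDTVLIPWYNGQCESWFNAEIVYP---------AYENLSMLHKSCAEITAWDKYDT---------NGQVIEMMSSWYEKWHANFRNPDTKTTYAVPLSYMCRFFEYWIDEIDGWVNYDDGCYFKFYEM-----RNNTKWVIKRWCCFWKMMYNGSTQQHRDKWYTSSIRFERLFSWNTNDRMWKEMKNHGDYEGFTINTEQFPHAQPRWQVDWWCRQVWLRWGAEKIAFFPFYEYSSMFAGMCDDPCAKGMWVLNTRINSENSFEWMHSAFRTKYWTVAAMHVGDAGNDRGGNVERGSDRTQSSYVKERMMHNFSMRCTKTANCRSTSSPTTFSHTGCPGVTTKGSYDHPSAKNLTTN
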