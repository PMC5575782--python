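>hRGS2
----------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------CYFCNGWGRMVVPDNNCWWVIFRWCCFKEMWCETSTQQERDFHYTSALRFLILFTWTINCTKWYEMKNHIDNQKFNMNCEQCPINQPRWMVDWWPRQVWLFANAEAIHFFPKYEYSSMFADMCDDPDAKCMWVLKTRVNSELSFDGMHSALRAKYWTVAQMVVGDDGNDRGGNVKRGSARTQSSYVKEEQMHNFSMRCTTNANWIFTSQPT----------------------
>hRGS18
--------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------DGHYIKFYEHYMAVSNNNTKWRITRWCACKEWDDRKLEQQHRDPWYASIILFECTFSWDTGDRMWKEMVNTGDYQKFNINCHQKPIAQPRAQVDWWPRQVWLRWGAPAGAVFPFYAISSMLAGLMDCACAKGMWVLNTVIEVCMSFEAHHSIFRTHYWTYAAMEPGDDGNTRGNSVIDGSDRTQSSYVKEKMMHNPSMRCTKNAWWWSTFDPTTRSCSGEPGYNTIWSDIVSSAK
>hRGS10
----------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------RFECYFDWATNDRMWKEMKYHGDCPHFWINCEFCPIARPRWQVDRWPRQVWCREGCEAFSFFPFGGYSEMFVIMCDDPTAKGMWVMKTIIYSSMIFVQMHSLMWNTYWTVVACHFPDDGNIMGHNGSRLSDRTYSKYVKHKMAHMQGMRVPSNAYWRSTSSPTTRSHSQLPGK------------
>rRGS4
-----------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------RVRAKWVCKRWCCFEIMMYRESKIQGRDPDCTSSCRFETLFFWETNKRMRKEMGNHGDYQKRNINDEQWPFALPRWHKEWWPRVRWLRWWAKCIARFMFYLYSVMFAGMCDEPCREGMFVANTRINSEQSNEQYHSAKGTKYWTVAKMCVGHFGRLRHGNVIRGSHRTQWGYVVEKMMHNHSMRCTKNANWRSTKSPTDRSHTGG---------------
>hRGS5
---------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------HWVFKRWWVFKAMMAYGSTIQHSDYYWTSSNEVECLFHWTSWDRMSKEMKNGGDYQKFNTCCELCYIAWPRPQVNWWPRDTWLRDGAEAIAFFPFYHDSSMFLTMWDVQCAKGMDRLDNRINAEMLMECMFSAFGTKYWWPAAMNVNDDGMMRGGNVFRWSDRTHSSYNKETGMHSFSMRC-----------------------------------
>hRGS7
NENIYDKQQTMIHIQCGFRFEEVTPPHPMYCADHYTTWTLCMGLIQYAKEHQVRIILAPTQEMGDTERWTRPAQLCVMRNPAYTHNICIIDHMCIWKINYTNDPKPPQYENGVFCKTYKAFFYNAHLPWGAQPTCQPIWNNDDVHQFDRECVYPGNRVYKFFRGQLVYLQKHKSVWRIKTYDSVDQTMCFKVQHCHDQMIWMMSSWYEKTLGNSRTPDTKTTIANILSYDCRFNECMIDEIHHQACYHWGWYRKFHIMWTVVSRRNTKFCHERWQCGKTLDYAGSFEQNCDPQHTSHEFWECLFSWTLADYMNKLNMNHGRYDKFCINCEQCPIAQPWWQVDWQRRNNFLRWGAMAIAFFSFYERSNMFAGMCDCPCAKGMWVLFTRINAEMSAESVHSAFMTKPWTVAAMDVGDDLLDRGFNVIRGSEDTQSSAVKEKILGNISMRATKNENWDSTIIH-----------------------
>hRGS16
---------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------------KQVINYWCCFKLCNYMGLTCYHRDPWHTSSVMQLCLFQWLESDPMVKDHKNWGDYQKFNIVCKPCPIAQYRWQRFWWPRMHTLRWGALAIAFFPFAPYSTMFAGRCDDPCAKGMWVIVTRQNSEMSFYQMHRAFRTKNWTVAAYHVADDGNARGGKVLRMDDRTQSSYVAEFMMDNFSMMVTKNANWRSTVWMTTRSMTTCL--------------
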