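population,experiments,families,samples,location,latitude,longitude,elevation
412,I II,16,15,Guangdong Renhua,25°19′,113°55′,99
415,I II,20,15,Guangdong Kaiping,22°25′,112°43′,7
524,I II,22,15,Hainan Tunchang,19°24′,110°07′,160
525,I II,16,14,Hainan Wuzhishan,18°47′,109°29′,280
628,I II,10,15,Guangxi Guilin,25°16′,110°17′,166
739,I II,7,15,Yunnan Mengla,21°48′,101°15′,1010
741,I II,11,15,Yunnan Malipo,23°06′,104°40′,1180
842,I II,9,15,Guizhou Xingyi,25°03′,104°37′,1407
843,I II,26,15,Guizhou Ceheng,24°57′,105°41′,1117
844,I II,4,15,Guizhou Liping,26°13′,109°08′,618
102,I,,15,Fujian Yong'an,25°49′,117°06′,255
205,I,,15,Jiangxi Yudu,25°59′,115°25′,132
248,I,,15,Jiangxi Ruichang,29°40′,115°40′,18
307,I,,15,Hunan Dong'an,26°22′,111°14′,205
308,I,,15,Hunan Liuyang,28°9′,113°38′,124
310,I,,15,Hunan Yanling,26°27′,113°40′,200
631,I,,15,Guangxi Qinzhou,21°58′,108°39′,17
652,I,,15,Guangxi Du'an,23°55′,108° 6′,373
754,I,,14,Yunnan Chuxiong,25°2′,101°31′,2173
858,I,,15,Guizhou Zunyi,27°43′,106°55′,1168
959,I,,15,Zhejiang Lin'an,30°13′,119°43′,47
1060,I,,15,Sichuan Chengdu,30°34′,104° 3′,495
1061,I,,15,Sichuan Dazhou,31°12′,107°28′,593
1162,I,,15,Anhui Chuzhou,32°18′,118°19′,15
1363,I,,15,Hubei Jingmen,31°2′,112°11′,98
1464,I,,15,Shanxi Weinan,34°29′,109°30′,351
1565,I,,14,Gansu Longnan,33°24′,104°55′,1106
1666,I,,15,Hebei Baoding,38°52′,115°27′,22
1767,I,,15,Shandong Jinan,36°39′,117°7′,122
1768,I,,15,Shandong Tai'an,36°13′,117°6′,641
1869,I,,14,Henan Xuchang,34°2′,113°51′,71
103,II,1,,Fujian Zhangping,25°16′,117°26′,219
413,II,9,,Guangdong Yunan,22°48′,111°21′,22
416,II,7,,Guangdong Qingyuan,23°51′,113°31′,73
417,II,4,,Guangdong En'ping,23°18′,112°25′,17
418,II,3,,Guangdong Raoping,23°39′,117°00′,20
523,II,8,,Hainan Haikou,19°49′,110°15′,129
526,II,9,,Hainan Lingshui,18°39′,109°52′,79
629,II,18,,Guangxi Rong'an,25°13′,109°23′,226
630,II,19,,Guangxi Sanjiang,25°50′,109°34′,240
651,II,10,,Guangxi Qinzhou,21°58′,108°39′,250
740,II,3,,Yunnan Luoping,24°58′,104°26′,1415
753,II,4,,Yunnan Xichou,23°26′,104°40′,1217
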